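"""Unsupervised structure exploration: HCA, PCA and histology discordance.

Samples are clustered/projected over a selected gene panel on per-gene
standardized log2(FPKM + 1).  The dendrogram is always cut at k = 2 — the
tumor/normal dichotomy — and every sample whose condition disagrees with its
cluster's majority condition is reported, annotated with its (adjacent
tumor's) stage class, mirroring the discrepancy tables of histology-vs-
molecular-profile comparisons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage, to_tree
from scipy.spatial.distance import pdist

from .containers import ExpressionMatrix, SampleMetadata

log = logging.getLogger(__name__)


def _panel_zscores(
    matrix: ExpressionMatrix, gene_panel, log_transform: bool = True
) -> pd.DataFrame:
    """Per-gene standardized values over the panel (genes x samples).

    Constant genes carry no clustering information; their z-scores are set to
    zero (logged) instead of producing NaNs.
    """
    panel = list(gene_panel)
    if not panel:
        raise ValueError("gene panel is empty")
    sub = matrix.subset_genes(panel)
    X = sub.log2p1() if log_transform else sub.values
    arr = X.to_numpy(dtype=float)
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=0, keepdims=True)
    constant = sd[:, 0] == 0.0
    if constant.any():
        log.debug("%d constant gene(s) in panel set to zero z-score", constant.sum())
    sd[sd == 0.0] = 1.0
    return pd.DataFrame((arr - mean) / sd, index=X.index, columns=X.columns)


@dataclass
class HCAResult:
    """Agglomerative clustering of samples with the fixed k = 2 cut.

    ``assignments`` has one row per sample: cluster (1|2), majority_condition
    of the cluster, and concordant (sample condition equals that majority).
    ``degenerate`` flags cuts that failed to produce two non-empty clusters
    (e.g. all samples identical).
    """

    linkage_matrix: np.ndarray
    sample_ids: list[str] = field(default_factory=list)
    assignments: pd.DataFrame = field(default_factory=pd.DataFrame)
    degenerate: bool = False
    distance: str = "euclidean"
    method: str = "ward"

    def to_newick(self) -> str:
        """Serialize the dendrogram as a Newick string with branch lengths."""
        root = to_tree(self.linkage_matrix)

        def render(node, parent_dist):
            length = parent_dist - node.dist
            if node.is_leaf():
                return f"{self.sample_ids[node.id]}:{length:.6f}"
            left = render(node.left, node.dist)
            right = render(node.right, node.dist)
            return f"({left},{right}):{length:.6f}"

        return render(root, root.dist) + ";"


def hca(
    matrix: ExpressionMatrix,
    gene_panel,
    metadata: SampleMetadata,
    distance: str = "euclidean",
    method: str = "ward",
    log_transform: bool = True,
) -> HCAResult:
    """Hierarchical clustering of samples over a gene panel, cut at k = 2.

    Ward linkage is the default because the fixed two-group cut is read as a
    tumor/normal dichotomy: variance-minimizing merges produce balanced
    cuts, whereas average linkage can spend the cut isolating a single
    extreme sample (or pair) when a few samples carry unusually strong
    co-regulated programs.  Average/complete linkage remain available.

    Cluster labels are deterministic given input order: the cluster holding
    the first sample is labelled 1.  A cluster's majority condition breaks
    ties toward the condition of its first-encountered sample.
    """
    if matrix.n_samples < 2:
        raise ValueError("HCA requires at least 2 samples")
    Z = _panel_zscores(matrix, gene_panel, log_transform=log_transform)
    data = Z.to_numpy(dtype=float).T  # samples x genes
    D = pdist(data, metric=distance)
    L = linkage(D, method=method)
    raw = fcluster(L, t=2, criterion="maxclust")
    sample_ids = list(Z.columns)
    degenerate = len(np.unique(raw)) < 2
    # relabel: first sample's cluster -> 1
    labels = np.where(raw == raw[0], 1, 2)

    rows = []
    majority: dict[int, str] = {}
    for cl in (1, 2):
        members = [s for s, lab in zip(sample_ids, labels) if lab == cl]
        if not members:
            continue
        conds = [metadata.condition(s) for s in members]
        n_t, n_n = conds.count("tumor"), conds.count("normal")
        if n_t > n_n:
            majority[cl] = "tumor"
        elif n_n > n_t:
            majority[cl] = "normal"
        else:
            majority[cl] = conds[0]  # tie -> first-encountered sample's condition
    for s, lab in zip(sample_ids, labels):
        cond = metadata.condition(s)
        rows.append(
            {
                "sample_id": s,
                "cluster": int(lab),
                "majority_condition": majority[int(lab)],
                "concordant": cond == majority[int(lab)],
            }
        )
    assignments = pd.DataFrame(rows).set_index("sample_id")
    return HCAResult(
        linkage_matrix=L,
        sample_ids=sample_ids,
        assignments=assignments,
        degenerate=degenerate,
        distance=distance,
        method=method,
    )


@dataclass
class PCAResult:
    """Sample scores on the leading principal components.

    Components are orthonormal with non-increasing explained variance; each
    component's sign is fixed by making its largest-magnitude gene loading
    positive, so downstream assertions and plots are stable.
    """

    scores: pd.DataFrame  # samples x components
    components: pd.DataFrame  # components x genes
    explained_variance_ratio: np.ndarray


def pca(
    matrix: ExpressionMatrix,
    gene_panel,
    n_components: int = 2,
    scale: bool = False,
    log_transform: bool = True,
) -> PCAResult:
    """PCA of samples over a gene panel on (optionally scaled) centered
    log2(FPKM + 1)."""
    panel = list(gene_panel)
    sub = matrix.subset_genes(panel)
    if n_components < 1 or n_components > min(sub.n_genes, sub.n_samples):
        raise ValueError(
            f"n_components must lie in [1, {min(sub.n_genes, sub.n_samples)}]"
        )
    X = (sub.log2p1() if log_transform else sub.values).to_numpy(dtype=float).T
    X = X - X.mean(axis=0, keepdims=True)
    if scale:
        sd = X.std(axis=0, ddof=0, keepdims=True)
        sd[sd == 0.0] = 1.0
        X = X / sd
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    scores = U[:, :n_components] * s[:n_components]
    comps = Vt[:n_components]
    for k in range(n_components):
        j = int(np.argmax(np.abs(comps[k])))
        if comps[k, j] < 0:
            comps[k] = -comps[k]
            scores[:, k] = -scores[:, k]
    n = X.shape[0]
    ev = s**2 / max(n - 1, 1)
    total = ev.sum()
    ratio = ev[:n_components] / total if total > 0 else np.zeros(n_components)
    pc_names = [f"PC{k + 1}" for k in range(n_components)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=sub.sample_ids, columns=pc_names),
        components=pd.DataFrame(comps, index=pc_names, columns=panel),
        explained_variance_ratio=ratio,
    )


def group_dispersion(pca_result: PCAResult, metadata: SampleMetadata) -> dict:
    """Per-condition mean Euclidean distance to the condition centroid in
    score space — the heterogeneity comparison as a number."""
    out = {}
    for cond in ("tumor", "normal"):
        samples = [s for s in pca_result.scores.index if metadata.condition(s) == cond]
        if len(samples) < 2:
            raise ValueError(f"condition {cond!r} has fewer than 2 samples")
        pts = pca_result.scores.loc[samples].to_numpy(dtype=float)
        centroid = pts.mean(axis=0, keepdims=True)
        out[cond] = float(np.linalg.norm(pts - centroid, axis=1).mean())
    return out


@dataclass
class DiscordanceReport:
    """Samples whose condition disagrees with their cluster's majority.

    ``tumors_clustering_with_normals`` lists (sample, stage_class) for tumors
    in a normal-majority cluster; ``normals_clustering_with_tumors`` lists
    (sample, stage_class of the adjacent tumor) for normals in a
    tumor-majority cluster.  ``degenerate`` is set when the k = 2 cut failed,
    in which case both lists are empty rather than fabricated.
    """

    panel_name: str
    tumors_clustering_with_normals: pd.DataFrame
    normals_clustering_with_tumors: pd.DataFrame
    degenerate: bool = False


def discordance_report(
    hca_result: HCAResult, metadata: SampleMetadata, panel_name: str
) -> DiscordanceReport:
    """List every non-concordant sample with its stage-class annotation."""
    cols = ["sample_id", "stage_class"]
    empty = pd.DataFrame(columns=cols)
    if hca_result.degenerate:
        log.warning("discordance_report(%s): degenerate k=2 cut", panel_name)
        return DiscordanceReport(panel_name, empty, empty.copy(), degenerate=True)
    t_rows, n_rows = [], []
    for sample, row in hca_result.assignments.iterrows():
        if row["concordant"]:
            continue
        entry = {"sample_id": sample, "stage_class": metadata.stage_class(sample)}
        if metadata.condition(sample) == "tumor":
            t_rows.append(entry)
        else:
            n_rows.append(entry)
    return DiscordanceReport(
        panel_name,
        pd.DataFrame(t_rows, columns=cols),
        pd.DataFrame(n_rows, columns=cols),
        degenerate=False,
    )
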