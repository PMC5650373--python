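"""Signed Pearson co-expression (relevance) networks over DEGs.

The network of interest connects differentially expressed genes whose
pairwise Pearson correlation of log2(FPKM + 1) across the declared sample set
exceeds 0.8 in magnitude (strictly).  Edges carry the signed correlation and
a pos/neg sign class; genes left without any strong partner are excluded from
the node set.  Hub genes are the highest-degree nodes per direction, and
module-level relationships are summarized by eigengene correlations at the
same threshold.

Correlations are computed across all samples (tumor + normal) by default:
the strong co/anti-correlations among DEGs are largely driven by the
tumor-normal contrast, which pooling preserves.  A tumors-only or
normals-only mode is available.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, GeneSetCollection, SampleMetadata

log = logging.getLogger(__name__)

SAMPLE_SETS = ("all", "tumors", "normals")


def _select_samples(
    matrix: ExpressionMatrix, samples: str, metadata: SampleMetadata | None
) -> ExpressionMatrix:
    if samples == "all":
        return matrix
    if samples not in SAMPLE_SETS:
        raise ValueError(f"samples must be one of {SAMPLE_SETS}, got {samples!r}")
    if metadata is None:
        raise ValueError(f"samples={samples!r} requires metadata")
    cond = "tumor" if samples == "tumors" else "normal"
    ids = [s for s in matrix.sample_ids if s in metadata.sample_ids
           and metadata.condition(s) == cond]
    return matrix.subset_samples(ids)


@dataclass
class CorrelationMatrix:
    """Symmetric Pearson correlation matrix over a declared sample set."""

    values: pd.DataFrame
    sample_set: str = "all"
    n_samples: int = 0

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)


def correlation_matrix(
    matrix: ExpressionMatrix,
    genes=None,
    samples: str = "all",
    metadata: SampleMetadata | None = None,
    log_transform: bool = True,
) -> CorrelationMatrix:
    """Exact sample Pearson correlation of log2(FPKM + 1) gene profiles.

    Requires at least 3 samples in the chosen set; constant genes are dropped
    with a logged list (their correlation is undefined).
    """
    sub = _select_samples(matrix, samples, metadata)
    if genes is not None:
        sub = sub.subset_genes(list(genes))
    if sub.n_samples < 3:
        raise ValueError(
            f"correlation requires >= 3 samples, got {sub.n_samples}"
        )
    X = (sub.log2p1() if log_transform else sub.values).to_numpy(dtype=float)
    sd = X.std(axis=1)
    constant = sd == 0.0
    if constant.any():
        dropped = [g for g, c in zip(sub.gene_ids, constant) if c]
        log.warning(
            "correlation_matrix: dropped %d constant gene(s): %s%s",
            len(dropped), ", ".join(dropped[:10]),
            "..." if len(dropped) > 10 else "",
        )
        keep = [g for g, c in zip(sub.gene_ids, constant) if not c]
        sub = sub.subset_genes(keep)
        X = (sub.log2p1() if log_transform else sub.values).to_numpy(dtype=float)
    if sub.n_genes < 2:
        raise ValueError("correlation requires >= 2 non-constant genes")
    C = np.corrcoef(X)
    C = np.clip((C + C.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(C, 1.0)
    return CorrelationMatrix(
        values=pd.DataFrame(C, index=sub.gene_ids, columns=sub.gene_ids),
        sample_set=samples,
        n_samples=sub.n_samples,
    )


@dataclass
class CoexpressionNetwork:
    """Thresholded signed correlation network.

    Nodes carry ``direction`` (up/down from the DE call), ``log2_fc`` and
    ``fold_change``; edges carry the signed ``cc`` and a ``sign`` class
    (pos/neg).  Isolated genes are not part of the node set.
    """

    graph: nx.Graph
    threshold: float
    sample_set: str = "all"

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degree(self, gene: str) -> int:
        return int(self.graph.degree[gene])

    def edges_table(self) -> pd.DataFrame:
        rows = []
        for u, v, data in self.graph.edges(data=True):
            a, b = sorted((u, v))
            rows.append(
                {"source": a, "target": b, "cc": data["cc"], "sign": data["sign"]}
            )
        table = pd.DataFrame(rows, columns=["source", "target", "cc", "sign"])
        return table.sort_values(["source", "target"], kind="mergesort").reset_index(
            drop=True
        )

    def nodes_table(self) -> pd.DataFrame:
        rows = [
            {
                "gene": g,
                "direction": d.get("direction", "ns"),
                "degree": int(self.graph.degree[g]),
                "log2_fc": d.get("log2_fc", np.nan),
                "fold_change": d.get("fold_change", np.nan),
            }
            for g, d in self.graph.nodes(data=True)
        ]
        table = pd.DataFrame(
            rows, columns=["gene", "direction", "degree", "log2_fc", "fold_change"]
        )
        return table.sort_values("gene", kind="mergesort").reset_index(drop=True)


def build_network(
    cc: CorrelationMatrix, de: pd.DataFrame, threshold: float = 0.8
) -> CoexpressionNetwork:
    """Edge for every unordered gene pair with |cc| strictly above
    *threshold*; genes without any such partner are excluded."""
    if not 0.0 <= threshold < 1.0:
        raise ValueError(f"threshold must lie in [0, 1), got {threshold}")
    missing = [g for g in cc.gene_ids if g not in de.index]
    if missing:
        raise KeyError(
            f"correlation genes absent from DE table: {', '.join(missing[:10])}"
        )
    A = cc.values.to_numpy(dtype=float)
    genes = cc.gene_ids
    iu, ju = np.triu_indices(len(genes), k=1)
    strong = np.abs(A[iu, ju]) > threshold
    graph = nx.Graph()
    for i, j in zip(iu[strong], ju[strong]):
        val = float(A[i, j])
        graph.add_edge(genes[i], genes[j], cc=val, sign="pos" if val > 0 else "neg")
    for g in graph.nodes:
        graph.nodes[g]["direction"] = str(de.loc[g, "direction"])
        graph.nodes[g]["log2_fc"] = float(de.loc[g, "log2_fc"])
        graph.nodes[g]["fold_change"] = float(de.loc[g, "fold_change"])
    return CoexpressionNetwork(
        graph=graph, threshold=threshold, sample_set=cc.sample_set
    )


@dataclass
class HubReport:
    """Top-k degree-ranked genes per direction.

    Within each list degrees are non-increasing; ties break by larger
    |log2 fold change|, then lexicographic gene id.
    """

    up: pd.DataFrame
    down: pd.DataFrame
    k_per_direction: int

    @property
    def genes(self) -> list[str]:
        return list(self.up["gene"]) + list(self.down["gene"])


def select_hubs(network: CoexpressionNetwork, k_per_direction: int = 5) -> HubReport:
    """Rank nodes by degree separately among up- and down-regulated genes and
    keep the top k of each (all of them, with a warning, if fewer exist)."""
    if k_per_direction < 1:
        raise ValueError("k_per_direction must be >= 1")
    cols = ["gene", "degree", "log2_fc", "fold_change"]
    tables = {}
    for direction in ("up", "down"):
        rows = [
            {
                "gene": g,
                "degree": int(network.graph.degree[g]),
                "log2_fc": float(d["log2_fc"]),
                "fold_change": float(d["fold_change"]),
            }
            for g, d in network.graph.nodes(data=True)
            if d.get("direction") == direction
        ]
        table = pd.DataFrame(rows, columns=cols)
        if len(table) < k_per_direction:
            log.warning(
                "select_hubs: only %d %s-regulated node(s) for k=%d",
                len(table), direction, k_per_direction,
            )
        if len(table):
            table = table.sort_values(
                by=["degree", "log2_fc", "gene"],
                ascending=[False, True, True],
                key=lambda s: -s.abs() if s.name == "log2_fc" else s,
                kind="mergesort",
            )
        tables[direction] = table.head(k_per_direction).reset_index(drop=True)
    return HubReport(up=tables["up"], down=tables["down"], k_per_direction=k_per_direction)


def hub_neighborhood(
    network: CoexpressionNetwork, hubs: HubReport
) -> CoexpressionNetwork:
    """Induced subgraph on the hubs and their direct neighbors."""
    hub_genes = hubs.genes
    missing = [g for g in hub_genes if g not in network.graph]
    if missing:
        raise KeyError(f"hub genes absent from network: {', '.join(missing)}")
    nodes = set(hub_genes)
    for g in hub_genes:
        nodes.update(network.graph.neighbors(g))
    sub = network.graph.subgraph(nodes).copy()
    return CoexpressionNetwork(
        graph=sub, threshold=network.threshold, sample_set=network.sample_set
    )


def eigengene(
    matrix: ExpressionMatrix,
    genes,
    samples: str = "all",
    metadata: SampleMetadata | None = None,
    log_transform: bool = True,
) -> pd.Series:
    """First principal-component score series of a module's standardized
    log2 values, sign-fixed to correlate positively with the module's mean
    profile."""
    genes = list(genes)
    if len(genes) < 3:
        raise ValueError("eigengene requires a module of >= 3 genes")
    sub = _select_samples(matrix, samples, metadata).subset_genes(genes)
    X = (sub.log2p1() if log_transform else sub.values).to_numpy(dtype=float)
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=0, keepdims=True)
    sd[sd == 0.0] = 1.0
    Z = (X - mean) / sd
    U, s, Vt = np.linalg.svd(Z.T, full_matrices=False)
    score = U[:, 0] * s[0]
    mean_profile = Z.mean(axis=0)
    if np.corrcoef(score, mean_profile)[0, 1] < 0:
        score = -score
    return pd.Series(score, index=sub.sample_ids, name="eigengene")


def module_correlation(
    matrix: ExpressionMatrix,
    modules: GeneSetCollection,
    samples: str = "all",
    metadata: SampleMetadata | None = None,
    threshold: float = 0.8,
    log_transform: bool = True,
) -> pd.DataFrame:
    """Eigengene correlation between every pair of modules (self-pairs
    included), classified positive/negative/none at the threshold.

    Modules must be non-overlapping and hold >= 3 genes each.  The mean
    pairwise gene-gene correlation is co-reported so the eigengene-based
    classification is auditable.
    """
    if not 0.0 <= threshold < 1.0:
        raise ValueError(f"threshold must lie in [0, 1), got {threshold}")
    names = modules.names
    for name in names:
        if len(modules[name]) < 3:
            raise ValueError(f"module {name!r} has fewer than 3 genes")
    for a, b in itertools.combinations(names, 2):
        shared = modules[a] & modules[b]
        if shared:
            raise ValueError(
                f"modules {a!r} and {b!r} overlap: {', '.join(sorted(shared)[:5])}"
            )
    sub = _select_samples(matrix, samples, metadata)
    eigen = {
        name: eigengene(sub, sorted(modules[name]), log_transform=log_transform)
        for name in names
    }
    logx = (sub.log2p1() if log_transform else sub.values)
    rows = []
    for a, b in itertools.combinations_with_replacement(names, 2):
        if a == b:
            cc, mean_cc = 1.0, 1.0
        else:
            cc = float(np.corrcoef(eigen[a], eigen[b])[0, 1])
            Xa = logx.loc[sorted(modules[a])].to_numpy(dtype=float)
            Xb = logx.loc[sorted(modules[b])].to_numpy(dtype=float)
            full = np.corrcoef(np.vstack([Xa, Xb]))
            mean_cc = float(full[: len(Xa), len(Xa):].mean())
        if cc > threshold:
            cls = "positive"
        elif cc < -threshold:
            cls = "negative"
        else:
            cls = "none"
        rows.append(
            {
                "module_a": a,
                "module_b": b,
                "eigengene_cc": cc,
                "mean_pairwise_cc": mean_cc,
                "classification": cls,
            }
        )
    return pd.DataFrame(rows)
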