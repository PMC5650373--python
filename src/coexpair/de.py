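"""Paired tumor/normal differential expression.

The cascade mirrors the standard FPKM workflow: genes are first filtered on
mean abundance (strictly > 1 FPKM across all samples by default), tested with
a per-gene blocked ANOVA (condition + subject) on log2(FPKM + 1) — which with
two conditions is exactly the paired t-test — corrected with Benjamini–
Hochberg, and called differential when both the linear fold-change criterion
(strictly > 2, either direction) and the FDR criterion (q ≤ 0.05) hold.

Fold changes are reported on the linear FPKM scale as
(mean_T + ε) / (mean_N + ε) with ε = 1e-3, while tests run on the log scale:
linear ratios are what the field quotes, but raw-FPKM tests would be badly
heteroskedastic.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix, SampleMetadata

log = logging.getLogger(__name__)

DE_COLUMNS = (
    "mean_T",
    "mean_N",
    "fold_change",
    "log2_fc",
    "p_value",
    "q_value",
    "direction",
)


def filter_by_abundance(
    matrix: ExpressionMatrix, threshold: float = 1.0
) -> ExpressionMatrix:
    """Retain genes whose mean FPKM across all samples is strictly above
    *threshold* (default 1), preserving input order."""
    if threshold < 0:
        raise ValueError(f"abundance threshold must be >= 0, got {threshold}")
    if matrix.n_genes == 0:
        raise ValueError("expression matrix is empty")
    means = matrix.values.mean(axis=1)
    kept = matrix.values.index[means > threshold]
    return ExpressionMatrix(matrix.values.loc[kept])


def _paired_arrays(
    matrix: ExpressionMatrix, metadata: SampleMetadata
) -> tuple[np.ndarray, np.ndarray]:
    """Tumor and normal log2(FPKM+1) arrays aligned by subject (genes x pairs)."""
    pairs = metadata.pairs()
    missing = [
        s
        for s in pd.concat([pairs["tumor"], pairs["normal"]])
        if s not in matrix.values.columns
    ]
    if missing:
        raise KeyError(f"samples absent from matrix: {', '.join(missing)}")
    logx = np.log2(matrix.values.to_numpy(dtype=float) + 1.0)
    col_pos = {s: i for i, s in enumerate(matrix.sample_ids)}
    t_cols = [col_pos[s] for s in pairs["tumor"]]
    n_cols = [col_pos[s] for s in pairs["normal"]]
    return logx[:, t_cols], logx[:, n_cols]


def paired_anova(matrix: ExpressionMatrix, metadata: SampleMetadata) -> pd.Series:
    """Per-gene p-value for the condition effect in the two-factor blocked
    model (condition + subject) on log2(FPKM + 1).

    With two conditions the condition F statistic equals the squared paired-t
    statistic, so the returned p-values are paired-t p-values.  Genes with
    zero within-pair variance of differences get p = 1 with a logged flag
    rather than an exception.
    """
    lt, ln = _paired_arrays(matrix, metadata)
    n = lt.shape[1]
    if n < 2:
        raise ValueError("paired ANOVA requires at least 2 pairs")
    d = lt - ln
    mean_d = d.mean(axis=1)
    sd_d = d.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_stat = n * mean_d**2 / sd_d**2
    degenerate = sd_d == 0.0
    if degenerate.any():
        log.warning(
            "paired_anova: %d gene(s) with zero within-pair variance; p set to 1",
            int(degenerate.sum()),
        )
    p = np.where(degenerate, 1.0, stats.f.sf(f_stat, 1, n - 1))
    return pd.Series(p, index=matrix.values.index, name="p_value")


def oneway_anova(matrix: ExpressionMatrix, metadata: SampleMetadata) -> pd.Series:
    """Unpaired one-way ANOVA on log2(FPKM + 1) — the sensitivity-analysis
    alternative that ignores the subject blocking."""
    logx = np.log2(matrix.values.to_numpy(dtype=float) + 1.0)
    col_pos = {s: i for i, s in enumerate(matrix.sample_ids)}
    xt = logx[:, [col_pos[s] for s in metadata.samples("tumor")]]
    xn = logx[:, [col_pos[s] for s in metadata.samples("normal")]]
    if xt.shape[1] < 2 or xn.shape[1] < 2:
        raise ValueError("one-way ANOVA requires >= 2 samples per condition")
    nt, nn = xt.shape[1], xn.shape[1]
    grand = np.concatenate([xt, xn], axis=1).mean(axis=1)
    ss_between = nt * (xt.mean(1) - grand) ** 2 + nn * (xn.mean(1) - grand) ** 2
    ss_within = ((xt - xt.mean(1, keepdims=True)) ** 2).sum(1) + (
        (xn - xn.mean(1, keepdims=True)) ** 2
    ).sum(1)
    df_within = nt + nn - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        f_stat = ss_between / (ss_within / df_within)
    degenerate = ss_within == 0.0
    if degenerate.any():
        log.warning(
            "oneway_anova: %d gene(s) with zero within-group variance; p set to 1",
            int(degenerate.sum()),
        )
    p = np.where(degenerate, 1.0, stats.f.sf(f_stat, 1, df_within))
    return pd.Series(p, index=matrix.values.index, name="p_value")


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, mapped back to input order.

    q_(i) = min_{j >= i} (p_(j) · m / j), capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return np.array([])
    if not np.isfinite(p).all() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must be finite and lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fold_change(
    matrix: ExpressionMatrix,
    metadata: SampleMetadata,
    epsilon: float = 1e-3,
    method: str = "ratio_of_means",
) -> pd.DataFrame:
    """Per-gene tumor/normal fold change on the linear FPKM scale.

    ``ratio_of_means`` (default) reports (mean_T + ε) / (mean_N + ε);
    ``per_pair_geometric`` reports the geometric mean of the per-pair ratios
    (T_i + ε) / (N_i + ε).  Columns: mean_T, mean_N, fold_change, log2_fc.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    t_samples = metadata.samples("tumor")
    n_samples = metadata.samples("normal")
    if not t_samples or not n_samples:
        raise ValueError("both conditions must be present")
    mean_t = matrix.values[t_samples].mean(axis=1)
    mean_n = matrix.values[n_samples].mean(axis=1)
    if method == "ratio_of_means":
        fc = (mean_t + epsilon) / (mean_n + epsilon)
    elif method == "per_pair_geometric":
        pairs = metadata.pairs()
        t_arr = matrix.values[list(pairs["tumor"])].to_numpy(dtype=float)
        n_arr = matrix.values[list(pairs["normal"])].to_numpy(dtype=float)
        log_ratio = np.log2((t_arr + epsilon) / (n_arr + epsilon)).mean(axis=1)
        fc = pd.Series(2.0**log_ratio, index=matrix.values.index)
    else:
        raise ValueError(
            "method must be 'ratio_of_means' or 'per_pair_geometric', "
            f"got {method!r}"
        )
    return pd.DataFrame(
        {
            "mean_T": mean_t,
            "mean_N": mean_n,
            "fold_change": fc,
            "log2_fc": np.log2(fc),
        }
    )


def de_table(
    matrix: ExpressionMatrix,
    metadata: SampleMetadata,
    fc_threshold: float = 2.0,
    fdr_threshold: float = 0.05,
    epsilon: float = 1e-3,
    paired: bool = True,
    fc_method: str = "ratio_of_means",
) -> pd.DataFrame:
    """Full per-gene differential expression table.

    Columns: mean_T, mean_N, fold_change, log2_fc, p_value, q_value,
    direction (up/down/ns).  ``up`` requires fold_change strictly above
    *fc_threshold* and q ≤ *fdr_threshold*; ``down`` the reciprocal criterion.
    """
    if fc_threshold <= 0:
        raise ValueError("fc_threshold must be positive")
    out = fold_change(matrix, metadata, epsilon=epsilon, method=fc_method)
    p = paired_anova(matrix, metadata) if paired else oneway_anova(matrix, metadata)
    out["p_value"] = p
    out["q_value"] = bh_fdr(p.to_numpy())
    passes_fdr = out["q_value"] <= fdr_threshold
    up = (out["fold_change"] > fc_threshold) & passes_fdr
    down = (1.0 / out["fold_change"] > fc_threshold) & passes_fdr
    out["direction"] = np.where(up, "up", np.where(down, "down", "ns"))
    return out


def call_degs(
    de: pd.DataFrame, fc_threshold: float = 2.0, fdr_threshold: float = 0.05
) -> tuple[frozenset, frozenset]:
    """Partition genes into (up, down) sets by the two-criterion call.

    The sets are disjoint by construction: a gene cannot satisfy both
    fold_change > t and 1/fold_change > t for t >= 1.
    """
    if fc_threshold <= 0:
        raise ValueError("fc_threshold must be positive")
    passes_fdr = de["q_value"] <= fdr_threshold
    up = de.index[(de["fold_change"] > fc_threshold) & passes_fdr]
    down = de.index[(1.0 / de["fold_change"] > fc_threshold) & passes_fdr]
    return frozenset(up), frozenset(down)


def volcano_table(de: pd.DataFrame) -> pd.DataFrame:
    """Deterministic volcano coordinates: (gene, log2_fc, neg_log10_p,
    direction).  p = 0 is floored at the smallest positive normal float."""
    floor = np.finfo(float).tiny
    p = np.clip(de["p_value"].to_numpy(dtype=float), floor, None)
    return pd.DataFrame(
        {
            "gene": de.index,
            "log2_fc": de["log2_fc"].to_numpy(),
            "neg_log10_p": -np.log10(p),
            "direction": de["direction"].to_numpy(),
        }
    ).set_index("gene")
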