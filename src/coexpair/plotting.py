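"""Convenience plots (volcano, PCA scatter). Not a tested numeric surface."""

from __future__ import annotations

from .containers import SampleMetadata
from .structure import PCAResult

_COLORS = {"up": "#c0392b", "down": "#2980b9", "ns": "#bbbbbb"}


def volcano_plot(de, ax=None):
    """Volcano plot of a DE table: log2 fold change vs -log10 p, colored by
    direction call."""
    import matplotlib.pyplot as plt

    from .de import volcano_table

    coords = volcano_table(de)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    for direction in ("ns", "up", "down"):
        sub = coords[coords["direction"] == direction]
        ax.scatter(sub["log2_fc"], sub["neg_log10_p"], s=4,
                   c=_COLORS[direction], label=direction, linewidths=0)
    ax.set_xlabel("log2 (T/N)")
    ax.set_ylabel("-log10 p")
    ax.legend(frameon=False, fontsize=8)
    return ax


def pca_plot(pca_result: PCAResult, metadata: SampleMetadata, ax=None):
    """PC1/PC2 scatter of samples colored by condition."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4))
    scores = pca_result.scores
    for cond, color in (("tumor", "#c0392b"), ("normal", "#2980b9")):
        ids = [s for s in scores.index if metadata.condition(s) == cond]
        ax.scatter(scores.loc[ids, "PC1"], scores.loc[ids, "PC2"], s=12,
                   c=color, label=cond, linewidths=0)
    evr = pca_result.explained_variance_ratio
    ax.set_xlabel(f"PC1 ({evr[0]:.1%})")
    if len(evr) > 1:
        ax.set_ylabel(f"PC2 ({evr[1]:.1%})")
    ax.legend(frameon=False, fontsize=8)
    return ax
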