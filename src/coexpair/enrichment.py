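"""Hypergeometric over-representation of gene sets.

Self-contained replacement for web-service GO/pathway enrichment: the query
(e.g. upregulated DEGs) is tested against user-supplied GMT collections with
the one-sided hypergeometric tail P[X >= k], BH-corrected across all tested
sets.  The universe is the set of genes that were actually eligible for the
query (by default, the abundance-filtered genes), not the whole genome.
"""

from __future__ import annotations

import logging

import pandas as pd
from scipy.stats import hypergeom

from .containers import GeneSetCollection
from .de import bh_fdr

log = logging.getLogger(__name__)

ENRICHMENT_COLUMNS = (
    "set_name",
    "overlap",
    "set_size",
    "query_size",
    "universe_size",
    "p_value",
    "q_value",
    "enriched",
)


def enrich(
    query,
    universe,
    sets: GeneSetCollection,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Over-representation of each gene set in *query* against *universe*.

    Sets are intersected with the universe before testing; sets with empty
    intersection are dropped (logged).  p = P[X >= k] for X ~
    Hypergeom(N=|universe|, K=|set ∩ universe|, n=|query|); q is BH across
    the tested sets; ``enriched`` means q strictly below *fdr_threshold*.
    Rows are sorted by (q, p, name).
    """
    query = frozenset(query)
    universe = frozenset(universe)
    stray = sorted(query - universe)
    if stray:
        raise ValueError(f"query genes outside the universe: {', '.join(stray)}")
    tested = sets.restrict_to(universe)
    N, n = len(universe), len(query)
    rows = []
    for name in tested.names:
        members = tested[name]
        K = len(members)
        k = len(members & query)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {
                "set_name": name,
                "overlap": k,
                "set_size": K,
                "query_size": n,
                "universe_size": N,
                "p_value": min(p, 1.0),
            }
        )
    if not rows:
        return pd.DataFrame(columns=list(ENRICHMENT_COLUMNS))
    table = pd.DataFrame(rows)
    table["q_value"] = bh_fdr(table["p_value"].to_numpy())
    table["enriched"] = table["q_value"] < fdr_threshold
    table = table.sort_values(
        ["q_value", "p_value", "set_name"], kind="mergesort"
    ).reset_index(drop=True)
    return table[list(ENRICHMENT_COLUMNS)]


def direction_split_enrich(
    de: pd.DataFrame,
    sets: GeneSetCollection,
    universe=None,
    fdr_threshold: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run :func:`enrich` separately on the up- and down-regulated DEG sets.

    The universe defaults to every gene in the DE table (the abundance-
    filtered, tested genes).  An empty DEG set yields an empty table with a
    logged warning.
    """
    if universe is None:
        universe = frozenset(de.index)
    tables = []
    for direction in ("up", "down"):
        genes = frozenset(de.index[de["direction"] == direction])
        if not genes:
            log.warning("direction_split_enrich: no %s-regulated genes", direction)
            tables.append(pd.DataFrame(columns=list(ENRICHMENT_COLUMNS)))
            continue
        tables.append(enrich(genes, universe, sets, fdr_threshold=fdr_threshold))
    return tables[0], tables[1]
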