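"""Readers and writers for the external formats the pipeline touches.

Expression matrices and sample metadata travel as TSV (CSV behind a dialect
switch), gene sets as GMT, and networks leave as TSV edge lists, SIF or
GraphML for downstream graph viewers.  Every reader validates through the
containers so no malformed object enters the pipeline.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import pandas as pd

from .containers import ExpressionMatrix, GeneSetCollection, SampleMetadata

log = logging.getLogger(__name__)

_DIALECTS = {"tsv": "\t", "csv": ","}
NETWORK_FORMATS = ("tsv_edge_list", "sif", "graphml")


def _sep(dialect: str) -> str:
    try:
        return _DIALECTS[dialect]
    except KeyError:
        raise ValueError(
            f"unknown dialect {dialect!r}; supported: {', '.join(_DIALECTS)}"
        ) from None


# ---------------------------------------------------------------------------
# expression tables
# ---------------------------------------------------------------------------

def read_expression_table(path, dialect: str = "tsv") -> ExpressionMatrix:
    """Read a gene × sample abundance table.

    The first column holds gene ids, the header row sample ids.  Input
    ordering is preserved; duplicate ids, negative, blank or non-numeric
    cells raise a located error.
    """
    df = pd.read_csv(path, sep=_sep(dialect), index_col=0)
    return ExpressionMatrix(df)


def write_expression_table(matrix: ExpressionMatrix, path, dialect: str = "tsv") -> None:
    """Write at full float precision so read-back is bit-identical."""
    matrix.values.to_csv(path, sep=_sep(dialect), index_label="gene_id")


# ---------------------------------------------------------------------------
# sample metadata
# ---------------------------------------------------------------------------

def read_metadata(path, paired: bool = True, dialect: str = "tsv") -> SampleMetadata:
    df = pd.read_csv(path, sep=_sep(dialect))
    return SampleMetadata(df, paired=paired)


def write_metadata(metadata: SampleMetadata, path, dialect: str = "tsv") -> None:
    metadata.table.to_csv(path, sep=_sep(dialect), index=False)


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file (name, description, tab-separated members per line).

    Duplicate members within a set are deduplicated with a logged warning;
    a line without members raises an error carrying the line number.
    """
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            members = [m for m in fields[2:] if m]
            if len(fields) < 3 or not members:
                raise ValueError(f"GMT line {lineno}: set {fields[0]!r} has no members")
            name = fields[0]
            if name in sets:
                raise ValueError(f"GMT line {lineno}: duplicate set name {name!r}")
            unique = list(dict.fromkeys(members))
            if len(unique) < len(members):
                log.warning(
                    "GMT set %r: removed %d duplicate members",
                    name,
                    len(members) - len(unique),
                )
            sets[name] = unique
            descriptions[name] = fields[1]
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name in collection.names:
            members = sorted(collection[name])
            fh.write("\t".join([name, collection.description(name), *members]) + "\n")


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

def write_network(network, path, format: str = "tsv_edge_list") -> None:
    """Export a co-expression network for graph viewers.

    ``tsv_edge_list`` writes source/target/cc/sign rows (cc at 6 decimals);
    ``sif`` uses the interaction labels ``pos``/``neg``; ``graphml`` goes
    through networkx.  An empty network yields a header-only TSV (or an empty
    SIF) without error.
    """
    if format not in NETWORK_FORMATS:
        raise ValueError(
            f"unknown network format {format!r}; supported: {', '.join(NETWORK_FORMATS)}"
        )
    if format == "tsv_edge_list":
        network.edges_table().to_csv(
            path, sep="\t", index=False, float_format="%.6f"
        )
    elif format == "sif":
        with open(path, "w") as fh:
            for row in network.edges_table().itertuples(index=False):
                fh.write(f"{row.source}\t{row.sign}\t{row.target}\n")
    else:  # graphml
        nx.write_graphml(network.graph, path)


def write_node_table(network, path) -> None:
    """Write the per-node table (gene, direction, degree, fold change)."""
    network.nodes_table().to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_network(edges_path, nodes_path, threshold: float | None = None,
                 sample_set: str = "unknown"):
    """Rebuild a :class:`~coexpair.network.CoexpressionNetwork` from its
    exported edge-list and node TSVs."""
    from .network import CoexpressionNetwork

    edges = pd.read_csv(edges_path, sep="\t")
    nodes = pd.read_csv(nodes_path, sep="\t")
    graph = nx.Graph()
    for row in nodes.itertuples(index=False):
        graph.add_node(
            str(row.gene),
            direction=str(row.direction),
            log2_fc=float(row.log2_fc),
            fold_change=float(row.fold_change),
        )
    for row in edges.itertuples(index=False):
        graph.add_edge(str(row.source), str(row.target), cc=float(row.cc),
                       sign=str(row.sign))
    if threshold is None:
        ccs = edges["cc"].abs()
        threshold = float(ccs.min()) if len(ccs) else 0.0
    return CoexpressionNetwork(graph=graph, threshold=threshold, sample_set=sample_set)


def read_gene_list(path) -> list[str]:
    """Read a plain text gene panel, one id per line, ignoring blanks."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]
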