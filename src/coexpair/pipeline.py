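"""Config-driven orchestration of the full analysis cascade.

Stage order: simulate (or load) → abundance filter → differential expression
→ clustering/PCA → enrichment → co-expression network → hubs → module
correlation.  Every run writes a reproducibility manifest with the config
snapshot, input checksums, the per-stage gene funnel (genes in → genes out)
and a checksum of every output file.  Numeric outputs use fixed 6-decimal
formatting so identical seeds give byte-identical runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .containers import ExpressionMatrix, SampleMetadata
from .de import call_degs, de_table, filter_by_abundance, volcano_table
from .enrichment import direction_split_enrich
from .io import (
    read_expression_table,
    read_gmt,
    read_metadata,
    write_expression_table,
    write_metadata,
    write_network,
    write_node_table,
)
from .network import (
    build_network,
    correlation_matrix,
    hub_neighborhood,
    module_correlation,
    select_hubs,
)
from .simulate import SimulationConfig, config_from_dict, generate_cohort, write_truth
from .structure import discordance_report, group_dispersion, hca, pca

log = logging.getLogger(__name__)

STAGES = ("de", "cluster", "enrich", "network", "hubs", "modules")
#: stage -> stages it needs
DEPENDENCIES = {
    "cluster": ("de",),
    "enrich": ("de",),
    "network": ("de",),
    "hubs": ("network",),
    "modules": (),
}


class PipelineError(RuntimeError):
    pass


class StageError(PipelineError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run; defaults mirror the standard criteria
    (mean FPKM > 1, fold > 2, FDR ≤ 0.05, |cc| > 0.8, 5 hubs per direction)."""

    out_dir: str = "."
    seed: int = 0
    simulate: bool = True
    sim: dict = field(default_factory=dict)  # SimulationConfig overrides
    expression: str | None = None
    metadata: str | None = None
    gene_sets: str | None = None  # GMT for enrichment
    modules_gmt: str | None = None  # modules for module correlation
    min_fpkm: float = 1.0
    fc_threshold: float = 2.0
    fdr_threshold: float = 0.05
    epsilon: float = 1e-3
    paired: bool = True
    cc_threshold: float = 0.8
    k_hubs: int = 5
    enrich_fdr: float = 0.05
    sample_set: str = "all"
    n_pca_components: int = 2
    stages: dict = field(
        default_factory=lambda: {name: True for name in STAGES}
    )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown pipeline config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        return cfg

    def with_overrides(self, **kwargs) -> "PipelineConfig":
        """CLI flags win over the config file."""
        updates = {k: v for k, v in kwargs.items() if v is not None}
        return dataclasses.replace(self, **updates)

    def enabled(self, stage: str) -> bool:
        return bool(self.stages.get(stage, True))

    def validate(self) -> None:
        if self.min_fpkm < 0:
            raise ValueError("min_fpkm must be >= 0")
        if not 0.0 <= self.cc_threshold < 1.0:
            raise ValueError("cc_threshold must lie in [0, 1)")
        if not 0.0 <= self.fdr_threshold <= 1.0:
            raise ValueError("fdr_threshold must lie in [0, 1]")
        if self.fc_threshold <= 0:
            raise ValueError("fc_threshold must be positive")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        for stage in STAGES:
            if not self.enabled(stage):
                continue
            for dep in DEPENDENCIES.get(stage, ()):
                if not self.enabled(dep):
                    raise PipelineError(
                        f"stage {stage!r} requires stage {dep!r}, which is disabled"
                    )
        if not self.simulate and (self.expression is None or self.metadata is None):
            raise ValueError(
                "simulate=false requires expression and metadata paths"
            )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_snapshot(config: PipelineConfig) -> dict:
    snap = dataclasses.asdict(config)
    snap["out_dir"] = "."  # keep manifests location-independent
    return snap


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in dependency order; returns the manifest.

    Any stage error aborts with the stage name after writing a partial
    manifest to the output directory.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "software": {"name": "coexpair", "version": __version__},
        "seed": int(config.seed),
        "config": _config_snapshot(config),
        "inputs": {},
        "counts": {},
        "stages_run": [],
        "outputs": {},
    }
    outputs: list[Path] = []

    def track(path: Path) -> Path:
        outputs.append(path)
        return path

    def finalize() -> dict:
        for path in sorted(set(outputs)):
            manifest["outputs"][path.name] = _sha256(path)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
            fh.write("\n")
        return manifest

    current = "input"
    try:
        # ------------------------------------------------------------ input
        if config.simulate:
            sim_cfg = config_from_dict({"seed": config.seed, **config.sim})
            matrix, metadata, truth = generate_cohort(sim_cfg)
            write_expression_table(matrix, track(out / "expression.tsv"))
            write_metadata(metadata, track(out / "metadata.tsv"))
            write_truth(truth, track(out / "truth.json"))
        else:
            truth = None
            manifest["inputs"]["expression"] = _sha256(Path(config.expression))
            manifest["inputs"]["metadata"] = _sha256(Path(config.metadata))
            matrix = read_expression_table(config.expression)
            metadata = read_metadata(config.metadata, paired=config.paired)
        manifest["counts"]["genes_total"] = matrix.n_genes
        manifest["counts"]["samples"] = matrix.n_samples

        # ----------------------------------------------------------- filter
        current = "filter"
        abundant = filter_by_abundance(matrix, threshold=config.min_fpkm)
        manifest["counts"]["genes_abundant"] = abundant.n_genes

        # --------------------------------------------------------------- de
        de = None
        if config.enabled("de"):
            current = "de"
            de = de_table(
                abundant,
                metadata,
                fc_threshold=config.fc_threshold,
                fdr_threshold=config.fdr_threshold,
                epsilon=config.epsilon,
                paired=config.paired,
            )
            de.to_csv(
                track(out / "de.tsv"), sep="\t", index_label="gene",
                float_format="%.6g",
            )
            volcano_table(de).to_csv(
                track(out / "volcano.tsv"), sep="\t", float_format="%.6g"
            )
            up, down = call_degs(de, config.fc_threshold, config.fdr_threshold)
            manifest["counts"]["degs_up"] = len(up)
            manifest["counts"]["degs_down"] = len(down)
            manifest["counts"]["degs_total"] = len(up) + len(down)
            deg_panel = [g for g in de.index if g in up or g in down]
            manifest["stages_run"].append("de")

        # ---------------------------------------------------------- cluster
        if config.enabled("cluster"):
            current = "cluster"
            if not deg_panel:
                log.warning("cluster stage skipped: no DEGs called")
                manifest["counts"]["cluster_skipped_no_degs"] = True
            else:
                hca_res = hca(abundant, deg_panel, metadata)
                hca_res.assignments.to_csv(
                    track(out / "cluster_assignments.tsv"), sep="\t"
                )
                with open(track(out / "dendrogram.nwk"), "w") as fh:
                    fh.write(hca_res.to_newick() + "\n")
                report = discordance_report(hca_res, metadata, "deg_panel")
                report.tumors_clustering_with_normals.assign(
                    group="tumors_with_normals"
                ).pipe(
                    lambda a: pd.concat(
                        [a, report.normals_clustering_with_tumors.assign(
                            group="normals_with_tumors")]
                    )
                ).to_csv(track(out / "discordance.tsv"), sep="\t", index=False)
                n_comp = min(
                    config.n_pca_components, len(deg_panel), abundant.n_samples
                )
                pca_res = pca(abundant, deg_panel, n_components=n_comp)
                pca_res.scores.to_csv(
                    track(out / "pca_scores.tsv"), sep="\t",
                    index_label="sample_id", float_format="%.6f",
                )
                dispersion = group_dispersion(pca_res, metadata)
                manifest["counts"]["cluster_concordant"] = int(
                    hca_res.assignments["concordant"].sum()
                )
                manifest["counts"]["pca_dispersion_tumor"] = round(
                    dispersion["tumor"], 6
                )
                manifest["counts"]["pca_dispersion_normal"] = round(
                    dispersion["normal"], 6
                )
            manifest["stages_run"].append("cluster")

        # ----------------------------------------------------------- enrich
        if config.enabled("enrich"):
            current = "enrich"
            if config.gene_sets is None:
                log.info("enrich stage skipped: no gene-set collection supplied")
                manifest["counts"]["enrich_skipped_no_gmt"] = True
            else:
                manifest["inputs"]["gene_sets"] = _sha256(Path(config.gene_sets))
                sets = read_gmt(config.gene_sets)
                up_tbl, down_tbl = direction_split_enrich(
                    de, sets, fdr_threshold=config.enrich_fdr
                )
                up_tbl.to_csv(
                    track(out / "enrichment_up.tsv"), sep="\t", index=False,
                    float_format="%.6g",
                )
                down_tbl.to_csv(
                    track(out / "enrichment_down.tsv"), sep="\t", index=False,
                    float_format="%.6g",
                )
                manifest["counts"]["enriched_up"] = int(up_tbl["enriched"].sum()) if len(up_tbl) else 0
                manifest["counts"]["enriched_down"] = int(down_tbl["enriched"].sum()) if len(down_tbl) else 0
                manifest["stages_run"].append("enrich")

        # ---------------------------------------------------------- network
        network = None
        if config.enabled("network"):
            current = "network"
            if len(deg_panel) < 2:
                log.warning("network stage skipped: fewer than 2 DEGs")
                manifest["counts"]["network_skipped_no_degs"] = True
            else:
                cm = correlation_matrix(
                    abundant, genes=deg_panel, samples=config.sample_set,
                    metadata=metadata,
                )
                network = build_network(cm, de, threshold=config.cc_threshold)
                write_network(network, track(out / "network_edges.tsv"),
                              "tsv_edge_list")
                write_node_table(network, track(out / "network_nodes.tsv"))
                write_network(network, track(out / "network.sif"), "sif")
                write_network(network, track(out / "network.graphml"), "graphml")
                manifest["counts"]["network_input_genes"] = len(cm.gene_ids)
                manifest["counts"]["network_nodes"] = network.n_nodes
                manifest["counts"]["network_edges"] = network.n_edges
                manifest["stages_run"].append("network")

        # ------------------------------------------------------------- hubs
        if config.enabled("hubs") and network is not None:
            current = "hubs"
            hubs = select_hubs(network, k_per_direction=config.k_hubs)
            pd.concat(
                [hubs.up.assign(direction="up"), hubs.down.assign(direction="down")]
            ).to_csv(
                track(out / "hubs.tsv"), sep="\t", index=False, float_format="%.6f"
            )
            if hubs.genes:
                neighborhood = hub_neighborhood(network, hubs)
                write_network(
                    neighborhood, track(out / "hub_neighborhood_edges.tsv"),
                    "tsv_edge_list",
                )
                manifest["counts"]["hub_neighborhood_nodes"] = neighborhood.n_nodes
                manifest["counts"]["hub_neighborhood_edges"] = neighborhood.n_edges
            manifest["stages_run"].append("hubs")

        # ---------------------------------------------------------- modules
        if config.enabled("modules"):
            current = "modules"
            if config.modules_gmt is not None:
                manifest["inputs"]["modules_gmt"] = _sha256(Path(config.modules_gmt))
                modules = read_gmt(config.modules_gmt)
            elif config.simulate and truth is not None and truth.module_of:
                modules = truth.modules()
            else:
                modules = None
                log.info("modules stage skipped: no module collection available")
                manifest["counts"]["modules_skipped_no_gmt"] = True
            if modules is not None:
                summary = module_correlation(
                    abundant if all(
                        g in abundant.values.index
                        for name in modules.names for g in modules[name]
                    ) else matrix,
                    modules,
                    samples=config.sample_set,
                    metadata=metadata,
                    threshold=config.cc_threshold,
                )
                summary.to_csv(
                    track(out / "module_correlation.tsv"), sep="\t", index=False,
                    float_format="%.6f",
                )
                manifest["stages_run"].append("modules")
    except Exception as exc:  # partial manifest, then abort with stage name
        manifest["failed_stage"] = current
        finalize()
        raise StageError(current, exc) from exc

    return finalize()
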