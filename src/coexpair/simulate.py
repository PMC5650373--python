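"""Synthetic paired tumor/normal FPKM cohorts with a machine-readable truth.

The generator emulates the design of a paired bulk RNA-seq study: each of
``n_pairs`` subjects contributes one tumor and one normal sample, and gene
abundance on the log2 scale is the sum of

* a per-gene baseline (a configurable fraction of genes is forced to low
  abundance, mean FPKM < 1, and never receives planted effects),
* a per-gene, per-subject random effect shared by the two samples of a pair
  (this is what makes the paired design real),
* a condition effect — log2 of the planted fold change — added to tumor
  samples of truly differential genes,
* correlated module structure: per-sample latent factors drawn from a signed
  inter-module correlation matrix, added to module members with a fixed
  loading,
* hub programs: subject-level latent factors (program activity varies
  between patients and is shared by the two samples of a pair) to which one
  hub gene (strong loading) and its partner genes (moderate loading) are
  coupled, so that hub degree in the inferred network is an emergent,
  recoverable property while the paired contrast stays clean,
* i.i.d. Gaussian measurement noise (log-normal on the FPKM scale), with
  optional per-condition multipliers.

FPKM = 2 ** (log2 value).  One global seed drives deterministic substreams
per stage, so identical seeds give bit-identical cohorts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, GeneSetCollection, SampleMetadata

log = logging.getLogger(__name__)

TRUTH_FORMAT_VERSION = 1

#: grade mix of the emulated cohort: well / moderate / poor differentiated
GRADE_PROBS = (17 / 79, 36 / 79, 26 / 79)


def default_inter_module_corr(n_modules: int) -> np.ndarray:
    """Signed block structure: the first ``n_modules // 2`` modules form one
    sign group and the rest the other; |correlation| 0.9 throughout.

    R = 0.1 I + 0.9 s sᵀ with s ∈ {+1, −1}ⁿ, which is positive definite for
    any sign vector.
    """
    if n_modules <= 0:
        return np.zeros((0, 0))
    s = np.ones(n_modules)
    s[n_modules // 2:] = -1.0
    return 0.1 * np.eye(n_modules) + 0.9 * np.outer(s, s)


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters of the synthetic cohort.

    Defaults emulate the target design: 79 tumor/normal pairs, ~10,000 genes
    of which 35% sit below the FPKM 1 abundance cutoff, 10% of genes with
    true tumor/normal effects spanning 2- to 250-fold (log-uniform), five
    correlated modules with a 2-vs-3 signed split, planted hub programs, and
    a 2:1 high:low stage ratio.
    """

    n_pairs: int = 79
    n_genes: int = 10_000
    frac_de: float = 0.10
    fold_change_range: tuple[float, float] = (2.0, 250.0)
    n_modules: int = 5
    module_sizes: tuple[int, ...] | None = None  # None -> 200 genes each
    inter_module_corr: np.ndarray | None = None  # None -> signed block default
    intra_module_loading: float = 0.9
    #: (gene id, number of coupled partners, direction); direction optional
    hub_spec: tuple = (
        ("HUB-UP-1", 160, "up"),
        ("HUB-DN-1", 160, "down"),
    )
    hub_loading: float = 5.0
    partner_loading: float = 2.5
    hub_fold_range: tuple[float, float] = (32.0, 64.0)
    hub_partner_fold_range: tuple[float, float] = (4.0, 6.0)
    #: hub-program genes are kept well expressed so the log-scale program
    #: signal is not truncated by the +1 pseudocount at low abundance
    program_baseline_log2_range: tuple[float, float] = (8.0, 12.0)
    subject_sd: float = 1.0
    noise_sd: float = 0.5
    tumor_noise_multiplier: float = 1.0
    normal_noise_multiplier: float = 1.0
    baseline_log2_mean_range: tuple[float, float] = (0.0, 8.0)
    low_abundance_log2_range: tuple[float, float] = (-6.0, -1.5)
    frac_low_abundance: float = 0.35
    stage_high_fraction: float = 53 / 79
    #: subject ids whose *normal* sample receives the tumor condition effect
    tumor_like_normals: tuple[str, ...] = ()
    seed: int = 0

    def resolved_module_sizes(self) -> tuple[int, ...]:
        if self.module_sizes is not None:
            return tuple(int(m) for m in self.module_sizes)
        return (200,) * self.n_modules

    def resolved_inter_module_corr(self) -> np.ndarray:
        if self.inter_module_corr is None:
            return default_inter_module_corr(self.n_modules)
        return np.asarray(self.inter_module_corr, dtype=float)

    def validate(self) -> None:
        if self.n_pairs < 2:
            raise ValueError("n_pairs must be >= 2")
        for name in ("frac_de", "frac_low_abundance", "stage_high_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        lo, hi = self.fold_change_range
        if lo < 1 or hi < lo:
            raise ValueError("fold_change_range must satisfy 1 <= low <= high")
        sizes = self.resolved_module_sizes()
        if len(sizes) != self.n_modules:
            raise ValueError("module_sizes length must equal n_modules")
        if any(m < 1 for m in sizes):
            raise ValueError("module sizes must be positive")
        if sum(sizes) > self.n_genes:
            raise ValueError("module sizes sum exceeds n_genes")
        R = self.resolved_inter_module_corr()
        if R.shape != (self.n_modules, self.n_modules):
            raise ValueError("inter_module_corr must be n_modules x n_modules")
        if self.n_modules:
            if not np.allclose(R, R.T, atol=1e-10):
                raise ValueError("inter_module_corr must be symmetric")
            if not np.allclose(np.diag(R), 1.0, atol=1e-10):
                raise ValueError("inter_module_corr must have a unit diagonal")
            if np.linalg.eigvalsh(R).min() < -1e-8:
                raise ValueError("inter_module_corr is not positive semidefinite")


@dataclass
class SyntheticTruth:
    """Planted ground truth of a synthetic cohort.

    ``de_genes`` maps gene -> {"fold": linear fold (> 1), "direction": up|down};
    ``module_of`` maps gene -> module id; ``hub_genes`` lists per planted hub
    its direction, partner count and partner ids; ``factor_corr`` is the
    realized inter-module correlation matrix.
    """

    de_genes: dict = field(default_factory=dict)
    module_of: dict = field(default_factory=dict)
    hub_genes: list = field(default_factory=list)
    factor_corr: list = field(default_factory=list)
    seed: int = 0

    def de_set(self, direction: str | None = None) -> frozenset:
        if direction is None:
            return frozenset(self.de_genes)
        return frozenset(
            g for g, info in self.de_genes.items() if info["direction"] == direction
        )

    def modules(self) -> GeneSetCollection:
        sets: dict[str, list[str]] = {}
        for gene, module in self.module_of.items():
            sets.setdefault(module, []).append(gene)
        return GeneSetCollection(sets)


def write_truth(truth: SyntheticTruth, path) -> None:
    payload = {
        "format_version": TRUTH_FORMAT_VERSION,
        "seed": int(truth.seed),
        "de_genes": {
            g: {"fold": float(i["fold"]), "direction": str(i["direction"])}
            for g, i in truth.de_genes.items()
        },
        "module_of": {g: str(m) for g, m in truth.module_of.items()},
        "hub_genes": [
            {
                "gene": str(h["gene"]),
                "direction": str(h["direction"]),
                "n_partners": int(h["n_partners"]),
                "partners": [str(p) for p in h["partners"]],
            }
            for h in truth.hub_genes
        ],
        "factor_corr": [[float(x) for x in row] for row in truth.factor_corr],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_truth(path) -> SyntheticTruth:
    with open(path) as fh:
        payload = json.load(fh)
    version = payload.get("format_version")
    if version != TRUTH_FORMAT_VERSION:
        raise ValueError(
            f"truth file format version {version!r} not supported "
            f"(expected {TRUTH_FORMAT_VERSION})"
        )
    return SyntheticTruth(
        de_genes=payload["de_genes"],
        module_of=payload["module_of"],
        hub_genes=payload["hub_genes"],
        factor_corr=payload["factor_corr"],
        seed=int(payload["seed"]),
    )


def _normalize_hub_spec(hub_spec) -> list[tuple[str, int, str]]:
    out = []
    for i, entry in enumerate(hub_spec):
        if len(entry) == 3:
            gene, n_partners, direction = entry
        elif len(entry) == 2:
            gene, n_partners = entry
            direction = "up" if i % 2 == 0 else "down"
        else:
            raise ValueError("hub_spec entries must be (gene, n_partners[, direction])")
        if direction not in ("up", "down"):
            raise ValueError(f"hub direction must be up|down, got {direction!r}")
        out.append((str(gene), int(n_partners), direction))
    return out


def generate_cohort(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, SampleMetadata, SyntheticTruth]:
    """Draw one synthetic paired cohort.

    Returns the FPKM matrix (samples interleaved T1, N1, T2, N2, ...), the
    sample metadata and the planted truth.  Identical configs (including the
    seed) give bit-identical outputs.
    """
    config.validate()
    n_g, n_p = config.n_genes, config.n_pairs
    n_s = 2 * n_p

    ss = np.random.SeedSequence(config.seed)
    (ss_assign, ss_effects, ss_factors, ss_subject, ss_noise, ss_meta) = ss.spawn(6)
    rng_assign = np.random.default_rng(ss_assign)
    rng_effects = np.random.default_rng(ss_effects)
    rng_factors = np.random.default_rng(ss_factors)
    rng_subject = np.random.default_rng(ss_subject)
    rng_noise = np.random.default_rng(ss_noise)
    rng_meta = np.random.default_rng(ss_meta)

    gene_ids = np.array([f"G{i + 1:05d}" for i in range(n_g)], dtype=object)

    # --- baselines: a fixed fraction of genes forced below the FPKM 1 cutoff
    n_low = int(round(config.frac_low_abundance * n_g))
    low_idx = np.sort(rng_assign.choice(n_g, size=n_low, replace=False))
    is_low = np.zeros(n_g, dtype=bool)
    is_low[low_idx] = True
    baselines = np.empty(n_g)
    baselines[is_low] = rng_assign.uniform(*config.low_abundance_log2_range, size=n_low)
    baselines[~is_low] = rng_assign.uniform(
        *config.baseline_log2_mean_range, size=n_g - n_low
    )

    # --- planted condition effects (abundant genes only: effects in genes
    # below the detection cutoff would be unrecoverable by design)
    abundant_idx = np.flatnonzero(~is_low)
    n_de = int(round(config.frac_de * n_g))
    if n_de > len(abundant_idx):
        raise ValueError("frac_de exceeds the abundant-gene budget")
    de_idx = rng_assign.choice(abundant_idx, size=n_de, replace=False)
    n_up = (n_de + 1) // 2
    up_idx = de_idx[:n_up]
    down_idx = de_idx[n_up:]
    lo, hi = config.fold_change_range
    folds = np.exp(rng_effects.uniform(np.log(lo), np.log(hi), size=n_de))
    delta = np.zeros(n_g)
    delta[up_idx] = np.log2(folds[:n_up])
    delta[down_idx] = -np.log2(folds[n_up:])

    # --- hub programs drawn from same-direction DE genes
    hub_entries = _normalize_hub_spec(config.hub_spec)
    used = np.zeros(n_g, dtype=bool)
    hub_rows: list[int] = []
    partner_rows: list[np.ndarray] = []
    truth_hubs: list[dict] = []
    for gene_id, n_partners, direction in hub_entries:
        pool = up_idx if direction == "up" else down_idx
        pool = np.array([i for i in pool if not used[i]])
        if len(pool) < n_partners + 1:
            raise ValueError(
                f"not enough unused {direction}-regulated genes for hub {gene_id!r}"
            )
        chosen = rng_assign.choice(pool, size=n_partners + 1, replace=False)
        hub_i, partners_i = int(chosen[0]), chosen[1:]
        used[chosen] = True
        gene_ids[hub_i] = gene_id
        baselines[chosen] = rng_assign.uniform(
            *config.program_baseline_log2_range, size=n_partners + 1
        )
        # hub program genes carry strong fold changes (the strongly
        # deregulated programs the network is meant to recover); the hub
        # itself is the strongest, which also breaks degree ties in its favor
        hlo, hhi = config.hub_fold_range
        plo, phi = config.hub_partner_fold_range
        hf = np.exp(rng_effects.uniform(np.log(hlo), np.log(hhi)))
        pf = np.exp(rng_effects.uniform(np.log(plo), np.log(phi), size=n_partners))
        sign = 1.0 if direction == "up" else -1.0
        delta[hub_i] = sign * np.log2(hf)
        delta[partners_i] = sign * np.log2(pf)
        hub_rows.append(hub_i)
        partner_rows.append(partners_i)
        truth_hubs.append(
            {
                "gene": gene_id,
                "direction": direction,
                "n_partners": n_partners,
                "partners": list(gene_ids[partners_i]),
            }
        )

    # --- correlated modules among abundant non-DE genes
    sizes = config.resolved_module_sizes()
    R = config.resolved_inter_module_corr()
    module_pool = np.array(
        [i for i in abundant_idx if delta[i] == 0.0 and not used[i]]
    )
    if sum(sizes) > len(module_pool):
        raise ValueError(
            "module sizes exceed the abundant non-differential gene budget"
        )
    module_of_idx: dict[int, str] = {}
    module_rows: list[np.ndarray] = []
    if sizes:
        chosen = rng_assign.choice(module_pool, size=sum(sizes), replace=False)
        offset = 0
        for m, size in enumerate(sizes):
            rows = chosen[offset:offset + size]
            offset += size
            module_rows.append(rows)
            for i in rows:
                module_of_idx[int(i)] = f"M{m + 1}"

    # --- latent draws
    tumor_cols = np.arange(0, n_s, 2)
    normal_cols = np.arange(1, n_s, 2)
    is_tumor_col = np.zeros(n_s, dtype=bool)
    is_tumor_col[tumor_cols] = True

    log2x = np.tile(baselines[:, None], (1, n_s))

    if sizes:
        w, V = np.linalg.eigh(R)
        A = V * np.sqrt(np.clip(w, 0.0, None))
        Z = rng_factors.standard_normal((n_s, len(sizes)))
        F = Z @ A.T  # samples x modules, Corr(F) = R
        for m, rows in enumerate(module_rows):
            log2x[rows] += config.intra_module_loading * F[:, m][None, :]

    if hub_rows:
        # one program-activity draw per subject, shared within each pair
        U = np.repeat(rng_factors.standard_normal((n_p, len(hub_rows))), 2, axis=0)
        for h, (hub_i, partners_i) in enumerate(zip(hub_rows, partner_rows)):
            log2x[hub_i] += config.hub_loading * U[:, h]
            log2x[partners_i] += config.partner_loading * U[:, h][None, :]

    subject_eff = rng_subject.standard_normal((n_g, n_p)) * config.subject_sd
    log2x += np.repeat(subject_eff, 2, axis=1)

    noise = rng_noise.standard_normal((n_g, n_s)) * config.noise_sd
    noise[:, tumor_cols] *= config.tumor_noise_multiplier
    noise[:, normal_cols] *= config.normal_noise_multiplier
    log2x += noise

    # --- condition effect (and planted tumor-like normals)
    subjects = [f"S{i + 1}" for i in range(n_p)]
    unknown = set(config.tumor_like_normals) - set(subjects)
    if unknown:
        raise ValueError(f"tumor_like_normals not in cohort: {sorted(unknown)}")
    log2x[:, tumor_cols] += delta[:, None]
    for subj in config.tumor_like_normals:
        col = 2 * subjects.index(subj) + 1
        log2x[:, col] += delta

    fpkm = np.clip(2.0 ** log2x, 0.0, None)

    sample_ids = []
    for i in range(n_p):
        sample_ids.extend([f"T{i + 1}", f"N{i + 1}"])
    matrix = ExpressionMatrix(
        pd.DataFrame(fpkm, index=list(gene_ids), columns=sample_ids)
    )

    # --- metadata: stage (2:1 high:low by default) and grade per subject
    n_high = int(round(config.stage_high_fraction * n_p))
    high_subjects = set(rng_meta.choice(n_p, size=n_high, replace=False))
    stage_num = np.where(
        [i in high_subjects for i in range(n_p)],
        rng_meta.choice([3, 4], size=n_p),
        rng_meta.choice([1, 2], size=n_p),
    )
    grades = rng_meta.choice(["well", "moderate", "poor"], size=n_p, p=GRADE_PROBS)
    rows = []
    for i in range(n_p):
        for cond in ("tumor", "normal"):
            rows.append(
                {
                    "sample_id": f"T{i + 1}" if cond == "tumor" else f"N{i + 1}",
                    "subject_id": subjects[i],
                    "condition": cond,
                    "stage_numeric": int(stage_num[i]),
                    "grade": str(grades[i]),
                }
            )
    metadata = SampleMetadata(pd.DataFrame(rows), paired=True)

    de_truth = {}
    for i in np.concatenate([up_idx, down_idx]) if n_de else []:
        i = int(i)
        de_truth[str(gene_ids[i])] = {
            "fold": float(2.0 ** abs(delta[i])),
            "direction": "up" if delta[i] > 0 else "down",
        }
    truth = SyntheticTruth(
        de_genes=de_truth,
        module_of={str(gene_ids[i]): m for i, m in module_of_idx.items()},
        hub_genes=truth_hubs,
        factor_corr=[[float(x) for x in row] for row in R],
        seed=config.seed,
    )
    return matrix, metadata, truth


def config_from_dict(d: dict) -> SimulationConfig:
    """Build a :class:`SimulationConfig` from a plain dict (e.g. parsed YAML),
    coercing list-valued fields to the tuple/array types the dataclass expects."""
    known = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
    d = dict(d)
    for key in ("fold_change_range", "hub_partner_fold_range",
                "baseline_log2_mean_range", "low_abundance_log2_range",
                "module_sizes", "tumor_like_normals"):
        if key in d and d[key] is not None:
            d[key] = tuple(d[key])
    if d.get("hub_spec") is not None:
        d["hub_spec"] = tuple(tuple(e) for e in d["hub_spec"])
    if d.get("inter_module_corr") is not None:
        d["inter_module_corr"] = np.asarray(d["inter_module_corr"], dtype=float)
    return SimulationConfig(**d)
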