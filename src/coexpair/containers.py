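"""Validated in-memory containers for the paired-cohort expression pipeline.

Three containers travel through every stage:

* :class:`ExpressionMatrix` — a dense gene × sample table of non-negative
  abundances (FPKM scale).
* :class:`SampleMetadata` — per-sample annotation (subject pairing, tumor/normal
  condition, TNM stage, grade) with pairing validated up front.
* :class:`GeneSetCollection` — named gene sets (GMT-style) used for enrichment
  and module-level analyses.

Validation is total: a constructor either returns an object satisfying all of
its invariants or raises a located error; no partially valid object escapes.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

CONDITIONS = ("tumor", "normal")
GRADES = ("well", "moderate", "poor")
LOW_STAGES = (1, 2)
HIGH_STAGES = (3, 4)


def _duplicates(items: Iterable[str]) -> list[str]:
    seen: set[str] = set()
    dups: list[str] = []
    for x in items:
        if x in seen and x not in dups:
            dups.append(x)
        seen.add(x)
    return dups


def stage_class_of(stage_numeric: int) -> str:
    """Map a TNM stage (1-4) to the low/high dichotomy (1-2 low, 3-4 high)."""
    if stage_numeric in LOW_STAGES:
        return "low"
    if stage_numeric in HIGH_STAGES:
        return "high"
    raise ValueError(f"stage_numeric must be 1-4, got {stage_numeric!r}")


class ExpressionMatrix:
    """Gene × sample matrix of non-negative, finite abundances.

    Parameters
    ----------
    values
        DataFrame with gene ids as the index and sample ids as the columns.
        Identifiers are opaque, case-sensitive strings. Blank cells are a hard
        error — the matrix is dense by contract.
    """

    def __init__(self, values: pd.DataFrame):
        if not isinstance(values, pd.DataFrame):
            raise TypeError("ExpressionMatrix expects a pandas DataFrame")
        values = values.copy()
        values.index = values.index.astype(str)
        values.columns = values.columns.astype(str)
        dup_g = _duplicates(values.index)
        if dup_g:
            raise ValueError(f"duplicate gene ids: {', '.join(dup_g)}")
        dup_s = _duplicates(values.columns)
        if dup_s:
            raise ValueError(f"duplicate sample ids: {', '.join(dup_s)}")
        try:
            numeric = values.astype(float)
        except (TypeError, ValueError):
            self._raise_located_nonnumeric(values)
            raise  # pragma: no cover - _raise always raises first
        arr = numeric.to_numpy(dtype=float)
        bad = ~np.isfinite(arr)
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise ValueError(
                "missing or non-finite value at gene "
                f"{numeric.index[i]!r}, sample {numeric.columns[j]!r}"
            )
        neg = arr < 0
        if neg.any():
            i, j = map(int, np.argwhere(neg)[0])
            raise ValueError(
                f"negative value {arr[i, j]!r} at gene {numeric.index[i]!r}, "
                f"sample {numeric.columns[j]!r}"
            )
        self._values = numeric

    @staticmethod
    def _raise_located_nonnumeric(values: pd.DataFrame) -> None:
        for col in values.columns:
            coerced = pd.to_numeric(values[col], errors="coerce")
            bad = coerced.isna() & ~values[col].isna()
            if bad.any():
                gene = values.index[int(np.argmax(bad.to_numpy()))]
                raise ValueError(
                    f"non-numeric value at gene {gene!r}, sample {col!r}"
                )
        raise ValueError("non-numeric values in expression table")

    # -- basic accessors ---------------------------------------------------
    @property
    def values(self) -> pd.DataFrame:
        return self._values

    @property
    def gene_ids(self) -> list[str]:
        return list(self._values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self._values.columns)

    @property
    def n_genes(self) -> int:
        return self._values.shape[0]

    @property
    def n_samples(self) -> int:
        return self._values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self._values.shape

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ExpressionMatrix({self.n_genes} genes x {self.n_samples} samples)"

    # -- transforms and views ----------------------------------------------
    def log2p1(self) -> pd.DataFrame:
        """Return log2(value + 1), the working scale for tests and correlations."""
        return np.log2(self._values + 1.0)

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        genes = list(genes)
        missing = [g for g in genes if g not in self._values.index]
        if missing:
            raise KeyError(f"genes absent from matrix: {', '.join(missing)}")
        return ExpressionMatrix(self._values.loc[genes])

    def subset_samples(self, samples: Iterable[str]) -> "ExpressionMatrix":
        samples = list(samples)
        missing = [s for s in samples if s not in self._values.columns]
        if missing:
            raise KeyError(f"samples absent from matrix: {', '.join(missing)}")
        return ExpressionMatrix(self._values[samples])


class SampleMetadata:
    """Per-sample annotation table with the paired design validated up front.

    Required columns: ``sample_id``, ``subject_id``, ``condition``
    (tumor|normal).  Optional: ``stage_numeric`` (1-4), ``stage_class``
    (low|high; derived from ``stage_numeric`` when absent, checked for
    consistency when present), ``grade`` (well|moderate|poor).

    With ``paired=True`` (the default) every subject must contribute exactly
    one tumor and one normal sample.
    """

    REQUIRED = ("sample_id", "subject_id", "condition")

    def __init__(self, table: pd.DataFrame, paired: bool = True):
        df = table.copy()
        if df.index.name == "sample_id":
            df = df.reset_index()
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"metadata missing required columns: {', '.join(missing)}")
        df["sample_id"] = df["sample_id"].astype(str)
        df["subject_id"] = df["subject_id"].astype(str)
        df["condition"] = df["condition"].astype(str)
        dup = _duplicates(df["sample_id"])
        if dup:
            raise ValueError(f"duplicate sample ids: {', '.join(dup)}")
        bad_cond = sorted(set(df["condition"]) - set(CONDITIONS))
        if bad_cond:
            raise ValueError(
                f"condition must be one of {CONDITIONS}, got: {', '.join(bad_cond)}"
            )

        if "stage_numeric" in df.columns:
            df["stage_numeric"] = pd.array(
                pd.to_numeric(df["stage_numeric"], errors="raise"), dtype="Int64"
            )
            known = df["stage_numeric"].dropna()
            bad = known[~known.isin(LOW_STAGES + HIGH_STAGES)]
            if len(bad):
                raise ValueError(f"stage_numeric outside 1-4: {sorted(set(bad))}")
        else:
            df["stage_numeric"] = pd.array([pd.NA] * len(df), dtype="Int64")

        derived = df["stage_numeric"].map(
            lambda s: stage_class_of(int(s)) if pd.notna(s) else pd.NA
        )
        if "stage_class" in df.columns:
            given = df["stage_class"].where(df["stage_class"].notna(), pd.NA)
            conflict = (given.notna() & derived.notna()) & (given != derived)
            if conflict.any():
                offenders = df.loc[conflict, "sample_id"].tolist()
                raise ValueError(
                    "stage_class inconsistent with stage_numeric for samples: "
                    + ", ".join(offenders)
                )
            df["stage_class"] = given.where(given.notna(), derived)
        else:
            df["stage_class"] = derived
        bad_sc = sorted(set(df["stage_class"].dropna()) - {"low", "high"})
        if bad_sc:
            raise ValueError(f"stage_class must be low|high, got: {', '.join(bad_sc)}")

        if "grade" in df.columns:
            bad_gr = sorted(set(df["grade"].dropna()) - set(GRADES))
            if bad_gr:
                raise ValueError(
                    f"grade must be one of {GRADES}, got: {', '.join(bad_gr)}"
                )
        else:
            df["grade"] = pd.NA

        if paired:
            offenders = []
            for subject, grp in df.groupby("subject_id", sort=False):
                counts = grp["condition"].value_counts()
                if counts.get("tumor", 0) != 1 or counts.get("normal", 0) != 1:
                    offenders.append(subject)
            if offenders:
                raise ValueError(
                    "paired design requires exactly one tumor and one normal "
                    f"per subject; offending subjects: {', '.join(offenders)}"
                )

        self._table = df.set_index("sample_id", drop=False)
        self.paired = paired

    # -- accessors ---------------------------------------------------------
    @property
    def table(self) -> pd.DataFrame:
        return self._table

    @property
    def sample_ids(self) -> list[str]:
        return list(self._table.index)

    def __len__(self) -> int:
        return len(self._table)

    def samples(self, condition: str) -> list[str]:
        if condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        mask = self._table["condition"] == condition
        return list(self._table.index[mask])

    def condition(self, sample_id: str) -> str:
        return str(self._table.loc[sample_id, "condition"])

    def subject(self, sample_id: str) -> str:
        return str(self._table.loc[sample_id, "subject_id"])

    def pairs(self) -> pd.DataFrame:
        """One row per subject with its tumor and normal sample ids.

        Subjects are ordered by first appearance in the table.
        """
        if not self.paired:
            raise ValueError("pairs() requires a paired design")
        rows = []
        for subject, grp in self._table.groupby("subject_id", sort=False):
            tumor = grp.index[grp["condition"] == "tumor"][0]
            normal = grp.index[grp["condition"] == "normal"][0]
            rows.append((subject, tumor, normal))
        return pd.DataFrame(rows, columns=["subject_id", "tumor", "normal"])

    def stage_class(self, sample_id: str):
        """Stage class of the sample's subject (a normal inherits its adjacent
        tumor's stage when its own row carries none)."""
        own = self._table.loc[sample_id, "stage_class"]
        if pd.notna(own):
            return str(own)
        subject = self.subject(sample_id)
        grp = self._table[self._table["subject_id"] == subject]
        known = grp["stage_class"].dropna()
        return str(known.iloc[0]) if len(known) else None

    def with_swapped_conditions(self) -> "SampleMetadata":
        """Return a copy with tumor/normal labels exchanged (for symmetry checks)."""
        df = self._table.reset_index(drop=True).copy()
        df["condition"] = df["condition"].map({"tumor": "normal", "normal": "tumor"})
        return SampleMetadata(df, paired=self.paired)


class GeneSetCollection(Mapping):
    """Named, non-empty gene sets with optional per-set descriptions.

    Behaves as a read-only mapping from set name to a frozenset of gene ids;
    insertion order of sets is preserved.
    """

    def __init__(
        self,
        sets: Mapping[str, Iterable[str]],
        descriptions: Mapping[str, str] | None = None,
    ):
        self._sets: dict[str, frozenset] = {}
        self._descriptions: dict[str, str] = {}
        for name, members in sets.items():
            members = frozenset(str(m) for m in members)
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
            self._sets[str(name)] = members
            self._descriptions[str(name)] = (
                str(descriptions.get(name, "")) if descriptions else ""
            )

    def __getitem__(self, name: str) -> frozenset:
        return self._sets[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._sets)

    def __len__(self) -> int:
        return len(self._sets)

    @property
    def names(self) -> list[str]:
        return list(self._sets)

    def description(self, name: str) -> str:
        return self._descriptions[name]

    def restrict_to(self, universe: Iterable[str]) -> "GeneSetCollection":
        """Intersect every set with *universe*; sets left empty are dropped."""
        universe = frozenset(universe)
        kept: dict[str, frozenset] = {}
        dropped = 0
        for name, members in self._sets.items():
            inter = members & universe
            if inter:
                kept[name] = inter
            else:
                dropped += 1
        if dropped:
            log.info("restrict_to: dropped %d gene sets with empty intersection", dropped)
        return GeneSetCollection(kept, self._descriptions)
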