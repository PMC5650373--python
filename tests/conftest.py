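import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from coexpair import ExpressionMatrix, SampleMetadata

settings.register_profile("suite", deadline=None, max_examples=50, derandomize=True)
settings.load_profile("suite")


@pytest.fixture
def expr_3x4() -> ExpressionMatrix:
    return ExpressionMatrix(
        pd.DataFrame(
            [[2.0, 4.0, 1.0, 3.0], [0.5, 0.25, 0.75, 1.5], [10.0, 20.0, 5.0, 40.0]],
            index=["KLK6", "MMP7", "CA1"],
            columns=["T1", "N1", "T2", "N2"],
        )
    )


@pytest.fixture
def meta_2pairs() -> SampleMetadata:
    return SampleMetadata(
        pd.DataFrame(
            {
                "sample_id": ["T1", "N1", "T2", "N2"],
                "subject_id": ["S1", "S1", "S2", "S2"],
                "condition": ["tumor", "normal", "tumor", "normal"],
                "stage_numeric": [3, 3, 1, 1],
            }
        )
    )


def paired_cohort(n_genes=60, n_pairs=12, seed=0, effect=0.0, n_affected=0):
    """Hand-rolled paired log-normal cohort, independent of the package's own
    generator: per-gene baseline + subject effect + optional tumor shift."""
    rng = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(n_genes)]
    base = rng.uniform(1, 6, size=n_genes)
    subj = rng.normal(0, 1, size=(n_genes, n_pairs))
    noise = rng.normal(0, 0.4, size=(n_genes, 2 * n_pairs))
    log2x = np.repeat(subj, 2, axis=1) + base[:, None] + noise
    log2x[:n_affected, 0::2] += effect
    cols, rows = [], []
    for i in range(n_pairs):
        cols.extend([f"T{i+1}", f"N{i+1}"])
        rows.extend(
            [
                {"sample_id": f"T{i+1}", "subject_id": f"S{i+1}", "condition": "tumor"},
                {"sample_id": f"N{i+1}", "subject_id": f"S{i+1}", "condition": "normal"},
            ]
        )
    matrix = ExpressionMatrix(pd.DataFrame(2.0 ** log2x, index=genes, columns=cols))
    return matrix, SampleMetadata(pd.DataFrame(rows))


@pytest.fixture
def small_paired_cohort():
    return paired_cohort()
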