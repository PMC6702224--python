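import numpy as np
import pandas as pd
import pytest

from mirtemporal.io import ExpressionMatrix, SampleTable
from mirtemporal.synthetic import CohortConfig


@pytest.fixture(scope="session")
def small_config() -> CohortConfig:
    """Scaled-down cohort for fast end-to-end checks."""
    return CohortConfig(n_control=60, n_case=20, n_mirna=90, n_mrna=120, seed=17)


@pytest.fixture
def toy_counts() -> ExpressionMatrix:
    values = np.array([[10, 20, 30], [5, 5, 5], [100, 0, 1]])
    return ExpressionMatrix(["a", "b", "c"], ["s1", "s2", "s3"], values, "counts")


def make_case_control_table(n_per_arm: int, seed: int = 0) -> SampleTable:
    """Adult case/control metadata with balanced covariates."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_arm
    return SampleTable(
        pd.DataFrame(
            {
                "sample_id": [f"S{i:03d}" for i in range(n)],
                "age_years": rng.uniform(18, 72, n),
                "diagnosis": ["control"] * n_per_arm + ["case"] * n_per_arm,
                "sex": rng.choice(["M", "F"], n),
                "race": rng.choice(["AA", "CAUC"], n),
                "batch": rng.choice(["b1", "b2"], n),
            }
        )
    )


def simulate_nb_counts(
    n_features: int,
    table: SampleTable,
    log2fc: np.ndarray,
    dispersion: float = 0.1,
    seed: int = 0,
    base_range=(3.0, 8.0),
):
    """Independent NB counts per feature: mean = libsize * 2^(base + lfc*case) / 1e6.

    Returns (matrix, true library sizes); features are independent, so the
    supplied library size is the exact offset."""
    rng = np.random.default_rng(seed)
    n = len(table)
    lib = np.exp(rng.normal(np.log(2e5), 0.3, n))
    base = rng.uniform(*base_range, n_features)
    is_case = (table.data["diagnosis"] == "case").to_numpy()
    mu = lib[None, :] * 2.0 ** (base[:, None] + np.asarray(log2fc)[:, None] * is_case[None, :]) / 1e6
    counts = rng.poisson(rng.gamma(1.0 / dispersion, mu * dispersion))
    em = ExpressionMatrix(
        [f"m{i:04d}" for i in range(n_features)], table.sample_ids, counts, "counts"
    )
    return em, lib
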