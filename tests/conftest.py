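import numpy as np
import pandas as pd
import pytest

from cohortclust.synthetic import (
    CohortConfig,
    CountBlockConfig,
    IntensityBlockConfig,
    generate_cohort,
)


def small_config(seed: int = 11, **overrides) -> CohortConfig:
    """A fast cohort configuration for unit tests (not the study conditions)."""
    defaults = dict(
        n_participants=120,
        seed=seed,
        taxa_block=CountBlockConfig(n_features=80, n_shifted=10, depth_mean=20_000),
        gene_block=CountBlockConfig(n_features=120, n_shifted=15, depth_mean=30_000),
        metabolite_blocks={
            "fecal_mx": IntensityBlockConfig(n_features=60, n_shifted=8),
            "plasma_mx": IntensityBlockConfig(n_features=50, n_shifted=6),
        },
    )
    defaults.update(overrides)
    return CohortConfig(**defaults)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(small_config())


@pytest.fixture(scope="session")
def two_factor_items():
    """Continuous items with clean 2-factor simple structure, n=400."""
    rng = np.random.default_rng(42)
    n, per = 400, 5
    f = rng.standard_normal((n, 2))
    cols, data = [], []
    for j in range(2):
        for i in range(per):
            lam = 0.7
            cols.append(f"it{j}_{i}")
            data.append(lam * f[:, j] + np.sqrt(1 - lam ** 2) * rng.standard_normal(n))
    items = pd.DataFrame(np.column_stack(data), columns=cols)
    return items, f
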