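import numpy as np
import pytest

from neuroenergetics import (AgeGroupSplit, CohortConfig,
                             build_energetics_table, generate_regional_cohort)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_cohort():
    """A compact concordant cohort for fast downstream tests."""
    cfg = CohortConfig(n_subjects=16, n_regions=30, seed=7)
    return cfg, generate_regional_cohort(cfg)


@pytest.fixture(scope="session")
def small_energetics(small_cohort):
    cfg, ds = small_cohort
    table = build_energetics_table(ds)
    split = AgeGroupSplit.from_ages(ds.ages, cutoff=cfg.group_cutoff)
    return ds, table, split
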