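import numpy as np
import pytest

from microdiv import SimParams, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small two-visit cohort with default (HMP-like) generator settings."""
    return simulate_cohort(SimParams(n_hosts=12, seed=7))


@pytest.fixture(scope="session")
def small_tables(small_cohort):
    return small_cohort[0]


@pytest.fixture(scope="session")
def small_truth(small_cohort):
    return small_cohort[1]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
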