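import numpy as np
import pytest

from coopsignal.cohort import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One study-shaped cohort (4 x 85 participants, 20 rounds), fixed seed."""
    return generate_cohort(CohortConfig(seed=20240901))


@pytest.fixture(scope="session")
def small_cohort():
    """A small cohort for fast structural tests."""
    return generate_cohort(CohortConfig(n_per_cell=12, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
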