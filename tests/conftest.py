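import numpy as np
import pytest

from petnode import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (~180 patients, ~675 nodes)."""
    return generate_cohort(CohortConfig(seed=1))


@pytest.fixture(scope="session")
def small_cohort():
    """A small cohort for the slower classifier/CV paths."""
    return generate_cohort(CohortConfig(n_patients=60, seed=2))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
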