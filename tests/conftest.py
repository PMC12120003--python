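import numpy as np
import pytest

from ssmpattern import CohortParams, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Paper-scale synthetic cohort (n=178) with planted pattern and paths."""
    return generate_cohort(CohortParams(seed=7))


@pytest.fixture(scope="session")
def small_cohort():
    """Small cohort for fast structural tests."""
    return generate_cohort(CohortParams(seed=3, n_subjects=60))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
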