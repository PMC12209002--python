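import warnings

import numpy as np
import pytest
from hypothesis import settings

from capdyn.synthetic import CohortSpec, generate_cohort

warnings.filterwarnings("ignore", message="model1: dropping constant predictor")

settings.register_profile("ci", derandomize=True, database=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_cohort():
    """One default 22x2 synthetic cohort shared by read-only tests."""
    return generate_cohort(CohortSpec(seed=7))


@pytest.fixture(scope="session")
def small_cohort():
    """A fast small cohort for pipeline-level tests."""
    return generate_cohort(
        CohortSpec(n_subjects=8, n_frames=100, n_parcels=40, seed=3)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
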