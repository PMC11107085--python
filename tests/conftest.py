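import numpy as np
import pytest

from mlssim.cohort import CohortParams, standard_cohort
from mlssim.model import DEFAULT_CONSTANTS


@pytest.fixture(scope="session")
def cohort29():
    """The fixed 29-athlete reference cohort (19 men, 10 women)."""
    return standard_cohort()


@pytest.fixture(scope="session")
def quiet_params():
    """Cohort parameters with every instrument noise switched off."""
    return CohortParams(power_cv=0.0, lactate_sd=0.0, breath_noise_sd=0.0)


@pytest.fixture(scope="session")
def constants():
    return DEFAULT_CONSTANTS


@pytest.fixture()
def rng():
    return np.random.default_rng(20240507)
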