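import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")

from rsoct.datatypes import CohortSpec
from rsoct.synthetic import OCTGenParams, RamanGenParams, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


SMALL_SPEC = CohortSpec(
    n_subjects=6,
    n_healthy_samples=5,
    n_tumor_samples=7,
    mean_rs_records_per_sample=3.0,
    mean_oct_records_per_sample=3.0,
    seed=7,
)
SMALL_OCT = OCTGenParams(side=64)


@pytest.fixture(scope="session")
def small_cohort():
    """A small but fully hierarchical cohort shared across tests."""
    spectra, images, truth = generate_cohort(SMALL_SPEC, oct_params=SMALL_OCT)
    return SMALL_SPEC, spectra, images, truth
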