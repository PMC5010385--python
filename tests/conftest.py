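import numpy as np
import pytest

from memtag.preprocess import subtract_baseline
from memtag.schedule import generate_schedule
from memtag.synthcohort import CohortConfig, GenerativeParams, simulate_cohort


@pytest.fixture(scope="session")
def tt_acac_schedule():
    return generate_schedule("T-T", "ACAC")


@pytest.fixture(scope="session")
def tt_caca_schedule():
    return generate_schedule("T-T", "CACA")


@pytest.fixture(scope="session")
def small_tt_cohort():
    """T-T cohort, 4 participants per subgroup, default generative params."""
    return simulate_cohort(CohortConfig(groups=("T-T",), n_per_subgroup=4, seed=11))


@pytest.fixture(scope="session")
def small_tt_records(small_tt_cohort):
    return subtract_baseline(small_tt_cohort)


@pytest.fixture(scope="session")
def null_params():
    """No polarity modulation, no subject or baseline heterogeneity."""
    return GenerativeParams(m=0.0, sigma_subject=0.0, baseline_offset_sd=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
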