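import numpy as np
import pytest

from cpactivity import make_cohort
from cpactivity.cohort import SubjectProfile


@pytest.fixture(scope="session")
def tiny_cohort():
    """One subject per GMFCS level, fixed seed."""
    return make_cohort({"I": 1, "II": 1, "III": 1}, master_seed=11)


@pytest.fixture(scope="session")
def level1_profile():
    """A mild-impairment walker with a regular gait."""
    return SubjectProfile(
        subject_id="P1", gmfcs_level="I", step_frequency=2.0,
        step_amplitude=0.8, gait_irregularity=0.05,
        sum_movement_scale=0.06, sed_noise_scale=0.006, rng_seed=123,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
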