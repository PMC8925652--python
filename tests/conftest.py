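import numpy as np
import pytest

from tfs_assay.cohort import CohortConfig, LatentSubject


@pytest.fixture(scope="session")
def default_subject() -> LatentSubject:
    """A middle-of-the-road simulated subject."""
    return LatentSubject(
        subject="S000", theta_b=30.0, theta_m=14.0, lapse=0.05, gain=1.0,
        latency_shift=0.0, itc_log_midpoint=float(np.log(50.0)), itc_steepness=1.5,
        ffr_neural=0.05, ffr_preneural=0.10, masking_alpha=0.8,
    )


@pytest.fixture(scope="session")
def small_config() -> CohortConfig:
    """Reduced cohort sizes for fast unit tests."""
    return CohortConfig(n_subjects=8, n_cortical_trials=200, n_ffr_trials=2000,
                        n_itd_blocks=4, n_fm_blocks_per_ear=2)
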