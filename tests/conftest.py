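import logging

import pytest
from hypothesis import settings

from pbifpet.cohort import CohortConfig
from pbifpet.pipeline import RunConfig, run_full

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")

# the blood-volume clipping warning fires on every noisy early frame; keep
# test output readable
logging.getLogger("pbifpet.kinetics").setLevel(logging.ERROR)

#: study-scale seed used for the cohort-level checks
STUDY_SEED = 20210429


@pytest.fixture(scope="session")
def noisefree_run():
    """Full study replica with measurement noise off (inter-subject
    variability retained): 18 subjects, 5 test-retest pairs."""
    cfg = RunConfig(cohort=CohortConfig(seed=STUDY_SEED, noise_scale=0.0), write_curves=False)
    return run_full(cfg)


@pytest.fixture(scope="session")
def zerovar_run():
    """Replica with zero inter-subject variability and zero noise: every
    subject is an identical clone, so population curves must reproduce each
    excluded subject exactly."""
    cohort = CohortConfig(
        seed=3,
        noise_scale=0.0,
        weight_cv=0.0,
        dose_cv=0.0,
        aif_amplitude_cv=0.0,
        aif_rate_cv=0.0,
        t_peak_sd_min=0.0,
        subject_vt_cv=0.0,
        region_vt_cv=0.0,
        retest_ratio_cv=0.0,
        parent_cv=0.0,
    )
    return run_full(RunConfig(cohort=cohort, write_curves=False))


@pytest.fixture(scope="session")
def stochastic_run():
    """Replica at the documented default variability and noise levels."""
    return run_full(RunConfig(cohort=CohortConfig(seed=STUDY_SEED), write_curves=False))
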