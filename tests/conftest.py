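import numpy as np
import pytest

import restmotion as rm


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def default_cohort():
    """The default 27-subject cohort (15 PD / 12 healthy, 3 trials)."""
    return rm.generate_cohort(rm.CohortConfig(seed=7))


@pytest.fixture(scope="session")
def default_table(default_cohort):
    """108-feature table of the default cohort, one row per subject."""
    return rm.build_feature_table(default_cohort)


@pytest.fixture(scope="session")
def sample_recording(default_cohort):
    return default_cohort[0][1][0]


def tiny_config(seed=0, **overrides):
    """Cheap cohort for fast end-to-end tests: 12 subjects, 4 s trials."""
    defaults = dict(
        n_pd=6,
        n_healthy=6,
        n_hy1=3,
        trial_duration=4.0,
        n_trials=1,
        seed=seed,
        hy1_amp_range=(2.0, 3.0),
        hy2_amp_range=(3.0, 5.0),
    )
    defaults.update(overrides)
    return rm.CohortConfig(**defaults)


@pytest.fixture(scope="session")
def tiny_table():
    return rm.build_feature_table(rm.generate_cohort(tiny_config(seed=5)))


def zero_recording(n=750, rate=50.0):
    series = {s: np.zeros((n, 3)) for s in rm.SENSOR_NAMES}
    return rm.IMURecording(
        sampling_rate=rate, series=series, subject_id="z", group="healthy"
    )
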