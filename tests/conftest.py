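import numpy as np
import pytest

from aftrends.config import SimulationConfig, TrendConfig
from aftrends.timeline import DEFAULT_INDEX_DAY, make_timeline
from aftrends.synth import simulate_cohort


def build_timeline(patient_id="T1", burden=None, longest=None, activity=None,
                   observed=None, n_days=None, **kwargs):
    """Hand-rolled timeline with sensible defaults for untouched channels."""
    if burden is not None:
        n_days = len(burden)
    burden = np.zeros(n_days) if burden is None else np.asarray(burden, dtype=float)
    longest = burden.copy() if longest is None else np.asarray(longest, dtype=float)
    activity = (np.full(n_days, 150.0) if activity is None
                else np.asarray(activity, dtype=float))
    kwargs.setdefault("censor_day", n_days)
    return make_timeline(
        patient_id, np.arange(1, n_days + 1),
        {
            "af_burden_min": burden,
            "max_continuous_af_min": longest,
            "activity_min": activity,
            "vrate_day_bpm": np.full(n_days, 75.0),
            "vrate_night_bpm": np.full(n_days, 65.0),
            "hrv_sd_ms": np.full(n_days, 100.0),
        },
        observed=observed, **kwargs)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_cohort():
    """A modest simulated cohort shared by read-only tests."""
    cfg = SimulationConfig(n_patients=80, max_follow_up_days=365, seed=42)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def trend_config():
    return TrendConfig()
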