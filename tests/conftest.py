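import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "repro", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("repro")

from posturolab.signal_io import PlateSignal, TrialRecord


def make_plates(ap, ml, fs=120.0, weight=700.0, half_width=100.0):
    """Build a consistent plate pair whose weighted CoP equals (ap, ml)."""
    ap = np.asarray(ap, dtype=float)
    ml = np.asarray(ml, dtype=float)
    n = len(ap)
    fz = np.full(n, weight / 2.0)
    left = PlateSignal("left", fz, ml - half_width, ap, fs)
    right = PlateSignal("right", fz, ml + half_width, ap, fs)
    return left, right


def make_trial(ap, ml, fs=120.0, participant="P01", group="control",
               condition="EO_NoDT", kind="sway", events=None):
    left, right = make_plates(ap, ml, fs=fs)
    return TrialRecord(participant_id=participant, group=group,
                       condition=condition, trial_kind=kind,
                       plates=(left, right), events=events or [])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def sway_trial(rng):
    """A 30 s quiet-stance trial with mild correlated sway."""
    n = 3600
    # slow sway: smoothed noise, plus small jitter
    from scipy.ndimage import uniform_filter1d
    ap = uniform_filter1d(rng.normal(0, 8, n), 121) + rng.normal(0, 0.05, n)
    ml = uniform_filter1d(rng.normal(0, 8, n), 121) + rng.normal(0, 0.05, n)
    return make_trial(ap, ml)
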