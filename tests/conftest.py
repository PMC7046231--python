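import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from voa import simdata
from voa.recording import RawRecording

settings.register_profile(
    "default",
    max_examples=50,
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def quiet_profile():
    """A noiseless skilled profile: every channel collapses to its analytic ideal."""
    return simdata.SimulationProfile(
        group_label="skilled",
        duration_s=10.0,
        sample_rate_hz=20.0,
        ua_force_mean_n=0.4, ua_force_jitter_n=0.0,
        bp_force_mean_n=1.0, bp_force_jitter_n=0.0,
        tip_separation_mean_mm=5.0, tip_separation_sd_mm=0.0,
        tremor_accel_mm_s2=0.0, tremor_jitter_mm_s2=0.0,
        bleed_rate_ml_s=0.05, bleed_jitter_ml_s=0.0,
    )


@pytest.fixture
def small_profile():
    """A short noisy profile for fast stochastic tests."""
    return simdata.default_skilled_profile(duration_s=20.0, sample_rate_hz=20.0)


def make_recording(t, ua_pos=None, bp_pos=None, ua_force=None, bp_force=None,
                   blood_ml=None):
    """Recording with analytic channels; unspecified channels are benign."""
    t = np.asarray(t, dtype=float)
    n = len(t)
    zeros3 = np.zeros((n, 3))
    return RawRecording(
        t=t,
        ua_pos=zeros3 if ua_pos is None else np.asarray(ua_pos, float),
        bp_pos=zeros3 if bp_pos is None else np.asarray(bp_pos, float),
        ua_force=np.zeros(n) if ua_force is None else np.asarray(ua_force, float),
        bp_force=np.zeros(n) if bp_force is None else np.asarray(bp_force, float),
        blood_ml=np.zeros(n) if blood_ml is None else np.asarray(blood_ml, float),
    )
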