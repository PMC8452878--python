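import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def timeline():
    from pupilplr.protocol import build_default_timeline

    return build_default_timeline()


@pytest.fixture()
def flat_subject():
    """Healthy subject with equal 4-mm baselines and no noise."""
    from pupilplr.plr_model import PLRParameters, Subject

    return Subject(
        id="S1",
        age_years=40.0,
        sex="F",
        group="healthy",
        lesion_side="none",
        params=PLRParameters(
            baseline_right_mm=4.0,
            baseline_left_mm=4.0,
            latency_s=0.2,
            tau_fall_s=0.9,
            tau_rise_s=0.25,
            amplitude_mm=1.2,
            consensual_gain=1.0,
            tau_rec_s=1.0,
            noise_sd_mm=0.0,
        ),
    )


def scan_metrics(trace, eye, window):
    """Independent exhaustive sample-scan oracle for the three metrics.

    Pure-Python loop over samples; kept deliberately separate from the
    package implementation.
    """
    vals = trace.eye(eye)
    best_min, best_t = None, None
    base_max, rec_max = None, None
    for i in range(len(trace)):
        if trace.quality[i] != "ok":
            continue
        t, v = trace.time_s[i], vals[i]
        if window.onset_s <= t < window.offset_s:
            if best_min is None or v < best_min:
                best_min, best_t = v, t
        if window.baseline_window[0] <= t < window.baseline_window[1]:
            if base_max is None or v > base_max:
                base_max = v
        if window.recovery_window[0] <= t < window.recovery_window[1]:
            if rec_max is None or v > rec_max:
                rec_max = v
    return {
        "miosis_rate": best_min / base_max,
        "miosis_time_s": best_t - window.onset_s,
        "mydriasis_rate": best_min / rec_max,
    }
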