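import numpy as np
import pytest

from conftest import scan_metrics
from pupilplr.cohort import generate_healthy_cohort
from pupilplr.metrics import (
    WindowDataError,
    compute_session_metrics,
    miosis_rate,
    miosis_time,
    mydriasis_rate,
    spontaneous_diameters,
)
from pupilplr.plr_model import simulate_trace
from pupilplr.protocol import build_default_timeline, stimulus_windows
from pupilplr.trace import PupilTrace


def make_trace(right, fs=60.0, left=None, quality=None):
    right = np.asarray(right, dtype=float)
    timeline = build_default_timeline()
    n = len(right)
    time_s = np.arange(n) / fs
    from pupilplr.trace import illumination_labels

    return PupilTrace(
        sample_rate_hz=fs,
        time_s=time_s,
        right_mm=right,
        left_mm=right.copy() if left is None else np.asarray(left, dtype=float),
        illumination=illumination_labels(timeline, time_s),
        quality=np.array(["ok"] * n, dtype=object) if quality is None else quality,
    )


@pytest.fixture(scope="module")
def windows():
    return stimulus_windows(build_default_timeline())


class TestMetricArithmetic:
    def test_miosis_rate_definition(self, windows):
        """Baseline 4 mm, minimum 2 mm during light -> rate 0.5."""
        fs = 60.0
        d = np.full(600, 4.0)
        d[150:200] = 2.0  # dip inside [2.5, 3.33) s
        rate = miosis_rate(make_trace(d), "right", windows[0])
        assert rate == pytest.approx(0.5)

    def test_flat_trace_rate_one_time_zero(self, windows):
        trace = make_trace(np.full(600, 4.0))
        assert miosis_rate(trace, "right", windows[0]) == 1.0
        assert miosis_time(trace, "right", windows[0]) == 0.0  # earliest tie wins
        assert mydriasis_rate(trace, "right", windows[0]) == 1.0

    def test_strictly_decreasing_minimum_at_window_end(self, windows):
        fs = 60.0
        d = 6.0 - 0.002 * np.arange(600)
        t = miosis_time(make_trace(d), "right", windows[0])
        assert t == pytest.approx(windows[0].duration_s - 1.0 / fs)

    def test_mydriasis_rate_with_partial_recovery(self, windows):
        """min 2.8, recovery toward 4 with tau 1 s: rate matches closed form."""
        fs = 60.0
        t = np.arange(600) / fs
        d = np.full(600, 4.0)
        stim = (t >= 2.0) & (t < 4.0)
        d[stim] = np.interp(t[stim], [2.0, 2.8, 4.0], [4.0, 2.8, 3.2])
        rec = t >= 4.0
        d[rec] = 4.0 - 0.8 * np.exp(-(t[rec] - 4.0) / 1.0)
        expected_max = 4.0 - 0.8 * np.exp(-(2.0 - 1.0 / fs) / 1.0)
        assert mydriasis_rate(make_trace(d), "right", windows[0]) == pytest.approx(
            2.8 / expected_max, abs=1e-9
        )

    def test_no_recovery_rate_one(self, windows):
        d = np.full(600, 4.0)
        d[120:] = 2.0  # constricts and never recovers
        assert mydriasis_rate(make_trace(d), "right", windows[0]) == 1.0


class TestQualityHandling:
    def test_blinks_excluded_from_extrema(self, windows):
        d = np.full(600, 4.0)
        d[130:140] = 1.0  # artefact dip inside stimulus window
        q = np.array(["ok"] * 600, dtype=object)
        q[130:140] = "blink"
        d2 = d.copy()
        d2[130:140] = np.nan
        trace = make_trace(d2, quality=q)
        assert miosis_rate(trace, "right", windows[0]) == 1.0

    def test_mostly_masked_window_fails(self, windows):
        q = np.array(["ok"] * 600, dtype=object)
        q[120:235] = "missing"  # >75 % of the stimulus window masked
        d = np.full(600, 4.0)
        d[120:235] = np.nan
        trace = make_trace(d, quality=q)
        with pytest.raises(WindowDataError, match="usable"):
            miosis_rate(trace, "right", windows[0])

    def test_session_metrics_error_names_eye_and_stimulus(self, windows):
        q = np.array(["ok"] * 600, dtype=object)
        q[360:480] = "missing"  # whole left-stimulus window
        d = np.full(600, 4.0)
        d[360:480] = np.nan
        trace = make_trace(d, quality=q)
        with pytest.raises(WindowDataError, match="left-eye stimulus"):
            compute_session_metrics(trace, build_default_timeline())


class TestSessionMetrics:
    def test_four_measurements_with_modes(self, timeline, flat_subject):
        trace, _ = simulate_trace(flat_subject, timeline, 60.0, seed=0)
        ms = compute_session_metrics(trace, timeline)
        assert [(m.eye.value, m.stimulated_eye.value, m.mode.value) for m in ms] == [
            ("right", "right", "direct"),
            ("left", "right", "indirect"),
            ("right", "left", "indirect"),
            ("left", "left", "direct"),
        ]

    def test_noiseless_metrics_equal_generator_truth(self, timeline):
        """Pipeline metrics on noiseless traces reproduce ground truth exactly."""
        for i, subject in enumerate(generate_healthy_cohort(25, seed=11)[:6]):
            from dataclasses import replace

            subject = replace(subject, params=replace(subject.params, noise_sd_mm=0.0))
            trace, truth = simulate_trace(subject, timeline, 60.0, seed=i)
            ms = compute_session_metrics(trace, timeline)
            for got, want in zip(ms, truth):
                assert got.miosis_rate == pytest.approx(want.miosis_rate, abs=1e-9)
                assert got.mydriasis_rate == pytest.approx(want.mydriasis_rate, abs=1e-9)
                assert abs(got.miosis_time_s - want.miosis_time_s) <= 1.0 / 60.0

    def test_direct_equals_indirect_for_symmetric_subject(self, timeline, flat_subject):
        trace, _ = simulate_trace(flat_subject, timeline, 60.0, seed=0)
        ms = compute_session_metrics(trace, timeline)
        w1 = [m for m in ms if m.stimulated_eye.value == "right"]
        assert w1[0].miosis_rate == pytest.approx(w1[1].miosis_rate, abs=1e-12)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(10))
    def test_metrics_equal_exhaustive_scan(self, timeline, seed):
        """Each metric equals a pure-Python exhaustive scan on noisy traces."""
        subject = generate_healthy_cohort(25, seed=seed)[seed % 25]
        trace, _ = simulate_trace(subject, timeline, 60.0, seed=seed)
        for w in stimulus_windows(timeline):
            for eye in ("right", "left"):
                want = scan_metrics(trace, eye, w)
                assert miosis_rate(trace, eye, w) == want["miosis_rate"]
                assert miosis_time(trace, eye, w) == want["miosis_time_s"]
                assert mydriasis_rate(trace, eye, w) == want["mydriasis_rate"]


class TestNoiseRobustness:
    def test_rate_error_bounded_by_extreme_value_arithmetic(self, timeline, flat_subject):
        """Mean |miosis-rate error| stays below 4*noise_sd/baseline.

        The baseline max gains ~2.5 sigma and the window min loses ~2 sigma
        from 120 iid noise samples, so 4 sigma / baseline bounds the mean
        absolute rate error.
        """
        from dataclasses import replace

        sd = 0.05
        subject = replace(flat_subject, params=replace(flat_subject.params, noise_sd_mm=sd))
        _, truth = simulate_trace(subject, timeline, 60.0, seed=0)
        want = truth[0].miosis_rate
        errs = []
        for seed in range(120):
            trace, _ = simulate_trace(subject, timeline, 60.0, seed=seed)
            w = stimulus_windows(timeline)[0]
            errs.append(abs(miosis_rate(trace, "right", w) - want))
        assert np.mean(errs) <= 4 * sd / 4.0


def test_spontaneous_diameter_is_first_phase_max(timeline, flat_subject):
    trace, _ = simulate_trace(flat_subject, timeline, 60.0, seed=0)
    sp = spontaneous_diameters(trace, timeline)
    assert sp["right"] == np.max(trace.right_mm[trace.time_s < 2.0])
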