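import math

import numpy as np
import pytest

from pupilplr.plr_model import (
    ModelError,
    PLRParameters,
    Subject,
    add_blink_artifacts,
    constriction_waveform,
    peak_time,
    simulate_trace,
)


def make_params(**kw):
    base = dict(
        baseline_right_mm=4.0,
        baseline_left_mm=4.0,
        latency_s=0.2,
        tau_fall_s=0.9,
        tau_rise_s=0.25,
        amplitude_mm=1.2,
        consensual_gain=1.0,
        tau_rec_s=1.0,
        noise_sd_mm=0.0,
    )
    base.update(kw)
    return PLRParameters(**base)


def make_subject(params, group="healthy", lesion="none"):
    return Subject("S", 40.0, "F", group, lesion, params)


class TestConstrictionWaveform:
    def test_zero_before_latency(self):
        p = make_params()
        assert constriction_waveform(0.0, p) == 0.0
        assert constriction_waveform(0.19, p) == 0.0

    def test_peak_location_and_value_match_closed_form(self):
        """Peak at L + (tf*tr/(tf-tr))ln(tf/tr) with value exactly A."""
        p = make_params()
        t_star = peak_time(0.9, 0.25)
        assert t_star == pytest.approx(
            (0.9 * 0.25 / 0.65) * math.log(0.9 / 0.25), abs=1e-12
        )
        t_peak = p.latency_s + t_star
        assert t_peak == pytest.approx(0.6434, abs=5e-4)
        assert constriction_waveform(t_peak, p) == pytest.approx(1.2, abs=1e-12)
        # dense 1-ms grid scan as independent check of the extremum
        grid = np.arange(0.0, 3.0, 0.001)
        vals = constriction_waveform(grid, p)
        assert abs(grid[np.argmax(vals)] - t_peak) <= 0.001
        assert np.max(vals) <= 1.2 + 1e-12

    def test_zero_amplitude_identically_zero(self):
        p = make_params(amplitude_mm=0.0)
        assert np.all(constriction_waveform(np.linspace(0, 5, 101), p) == 0.0)

    def test_continuity_at_latency(self):
        p = make_params()
        eps = 1e-9
        assert constriction_waveform(p.latency_s + eps, p) < 1e-6

    def test_equal_time_constants_rejected(self):
        with pytest.raises(ModelError):
            make_params(tau_fall_s=0.5, tau_rise_s=0.5)

    def test_negative_time_rejected(self):
        with pytest.raises(ModelError):
            constriction_waveform(-0.1, make_params())


class TestParameterValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            dict(baseline_right_mm=0.8),
            dict(baseline_left_mm=10.5),
            dict(amplitude_mm=4.5),
            dict(consensual_gain=-0.1),
            dict(tau_rec_s=0.0),
        ],
    )
    def test_invalid_parameters_rejected(self, kw):
        with pytest.raises(ModelError):
            make_params(**kw)

    def test_patient_without_lesion_rejected(self):
        with pytest.raises(ModelError):
            make_subject(make_params(), group="patient", lesion="none")


class TestSimulateTrace:
    def test_no_stimulus_response_is_flat(self, timeline):
        s = make_subject(make_params(amplitude_mm=0.0))
        trace, _ = simulate_trace(s, timeline, 60.0, seed=0)
        assert np.all(trace.right_mm == 4.0)
        assert np.all(trace.left_mm == 4.0)

    def test_consensual_symmetry_of_series(self, timeline):
        """Equal baselines and gain 1: eyes move identically."""
        s = make_subject(make_params())
        trace, _ = simulate_trace(s, timeline, 60.0, seed=0)
        np.testing.assert_allclose(trace.right_mm, trace.left_mm, atol=1e-12)

    def test_ground_truth_miosis_rate_closed_form(self, timeline):
        """Peak constriction inside the window: rate = (b - A)/b = 0.7."""
        s = make_subject(make_params())
        _, truth = simulate_trace(s, timeline, 60.0, seed=0)
        right_direct = next(
            m for m in truth if m.eye.value == "right" and m.mode.value == "direct"
        )
        # ground truth scans the sampling grid, so allow the grid-vs-peak gap
        assert right_direct.miosis_rate == pytest.approx(2.8 / 4.0, abs=1e-3)

    def test_ground_truth_consensual_symmetry(self, timeline):
        """Gain 1, equal eyes: direct and indirect ground truth coincide."""
        s = make_subject(make_params())
        _, truth = simulate_trace(s, timeline, 60.0, seed=0)
        w1 = [m for m in truth if m.stimulated_eye.value == "right"]
        direct = next(m for m in w1 if m.mode.value == "direct")
        indirect = next(m for m in w1 if m.mode.value == "indirect")
        assert direct.miosis_rate == pytest.approx(indirect.miosis_rate, abs=1e-12)
        assert direct.miosis_time_s == indirect.miosis_time_s

    def test_determinism(self, timeline):
        s = make_subject(make_params(noise_sd_mm=0.05))
        t1, g1 = simulate_trace(s, timeline, 60.0, seed=42)
        t2, g2 = simulate_trace(s, timeline, 60.0, seed=42)
        np.testing.assert_array_equal(t1.right_mm, t2.right_mm)
        np.testing.assert_array_equal(t1.left_mm, t2.left_mm)
        assert [m.miosis_rate for m in g1] == [m.miosis_rate for m in g2]

    def test_undersampled_rate_rejected(self, timeline):
        with pytest.raises(ModelError, match="undersample"):
            simulate_trace(make_subject(make_params()), timeline, 1.0, seed=0)

    def test_lesioned_eye_direct_amplitude_reduced(self, timeline):
        # right-side lesion so the lesioned eye's direct window is the first
        # stimulus, uncontaminated by recovery carry-over from earlier phases
        p = make_params(lesion_direct_factor=0.5)
        s = make_subject(p, group="patient", lesion="right")
        _, truth = simulate_trace(s, timeline, 60.0, seed=0)
        right_direct = next(
            m for m in truth if m.eye.value == "right" and m.mode.value == "direct"
        )
        left_indirect = next(
            m
            for m in truth
            if m.eye.value == "left" and m.stimulated_eye.value == "right"
        )
        # direct constriction halved on the lesioned eye, consensual untouched
        assert right_direct.min_mm == pytest.approx(4.0 - 0.6, abs=2e-3)
        assert left_indirect.min_mm == pytest.approx(4.0 - 1.2, abs=2e-3)


class TestBlinkArtifacts:
    def test_zero_rate_is_identity(self, timeline):
        s = make_subject(make_params(noise_sd_mm=0.02))
        trace, _ = simulate_trace(s, timeline, 60.0, seed=0)
        out = add_blink_artifacts(trace, 0.0, 0.2, seed=1)
        np.testing.assert_array_equal(out.right_mm, trace.right_mm)
        assert np.all(out.quality == "ok")

    def test_blink_masks_expected_sample_count(self, timeline):
        s = make_subject(make_params())
        trace, _ = simulate_trace(s, timeline, 30.0, seed=0)
        # find a seed realisation with exactly one blink event
        for seed in range(50):
            out = add_blink_artifacts(trace, 0.1, 0.2, seed=seed)
            n_blink = int(np.sum(out.quality == "blink"))
            if n_blink:
                break
        assert n_blink % 6 == 0  # 0.2 s at 30 Hz = 6 consecutive samples
        assert np.all(np.isnan(out.right_mm[out.quality == "blink"]))
        ok = out.quality == "ok"
        np.testing.assert_array_equal(out.right_mm[ok], trace.right_mm[ok])

    def test_determinism(self, timeline):
        s = make_subject(make_params())
        trace, _ = simulate_trace(s, timeline, 60.0, seed=0)
        a = add_blink_artifacts(trace, 0.5, 0.2, seed=9)
        b = add_blink_artifacts(trace, 0.5, 0.2, seed=9)
        np.testing.assert_array_equal(a.quality, b.quality)

    def test_overlong_blink_rejected(self, timeline):
        s = make_subject(make_params())
        trace, _ = simulate_trace(s, timeline, 60.0, seed=0)
        with pytest.raises(ModelError):
            add_blink_artifacts(trace, 0.1, 10.0, seed=0)
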