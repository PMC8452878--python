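"""Pupillary light reflex dynamics model and trace simulator.

The constriction evoked by a visible-light stimulus is modelled as a
latency-delayed difference of exponentials,

    c(t) = A * h(t - L) / h(t*) ,   h(s) = exp(-s/tau_fall) - exp(-s/tau_rise)

with ``tau_fall > tau_rise``.  ``h`` rises to its maximum at

    t* = (tau_fall * tau_rise / (tau_fall - tau_rise)) * ln(tau_fall/tau_rise)

and then partially decays ("pupil escape"), so the diameter minimum occurs
strictly inside a sustained stimulus and the time-to-minimum metric is
non-degenerate.  The normalisation makes the peak constriction exactly A mm.

After light-off (plus the same latency) the constriction relaxes
exponentially toward the resting diameter with time constant ``tau_rec``;
an optional rebound term transiently dilates the pupil *above* its resting
diameter (post-stimulus sympathetic overshoot), which is the behaviour that
produces markedly low mydriasis rates.

Consensual coupling: when the contralateral eye is stimulated, the same
waveform is applied scaled by ``consensual_gain``.  A lesioned eye responds
with slower-clock time constants scaled by ``lesion_speed_factor`` in both
modes and with its amplitude scaled by ``lesion_direct_factor`` under
direct stimulation only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .protocol import (
    Eye,
    Mode,
    ProtocolTimeline,
    StimulusWindow,
    classify_mode,
    stimulus_windows,
)
from .trace import (
    QUALITY_BLINK,
    QUALITY_OK,
    PupilTrace,
    illumination_labels,
)

#: Shape constants of the rebound (overshoot) waveform, seconds.  The
#: rebound is a normalised difference of exponentials peaking ~0.26 s after
#: recovery onset and mostly decayed by ~1.5 s, so it does not contaminate
#: the next stimulus's baseline phase.
REBOUND_TAU_FALL_S = 0.5
REBOUND_TAU_RISE_S = 0.15


class ModelError(ValueError):
    """Raised for invalid model parameters or simulation inputs."""


@dataclass(frozen=True)
class PLRParameters:
    """Per-subject pupil dynamics parameters.

    Parameters
    ----------
    baseline_right_mm, baseline_left_mm : float
        Resting diameters, each in (1, 10) mm.
    latency_s : float
        Onset delay of constriction and of post-offset recovery.
    tau_fall_s, tau_rise_s : float
        Time constants of the difference-of-exponentials constriction;
        ``tau_fall_s > tau_rise_s > 0``.
    amplitude_mm : float
        Peak direct constriction; must be smaller than either baseline.
    consensual_gain : float
        Scale of the indirect (contralateral) response, in [0, 1.5].
    tau_rec_s : float
        Recovery time constant after light-off.
    noise_sd_mm : float
        SD of additive, independent per-sample measurement noise.
    lesion_direct_factor, lesion_speed_factor : float
        Multipliers applied to a lesioned eye's direct amplitude and to its
        constriction time constants (both modes); 1 = no lesion effect.
    rebound_frac : float
        Peak post-stimulus overshoot as a fraction of the eye's resting
        diameter; 0 disables the rebound.
    lesion_rebound_boost : float
        Extra multiplier on the rebound after *direct* stimulation of a
        lesioned eye (exaggerated redilation on the lesion side); 1 = none.
    """

    baseline_right_mm: float
    baseline_left_mm: float
    latency_s: float = 0.2
    tau_fall_s: float = 1.4
    tau_rise_s: float = 0.3
    amplitude_mm: float = 1.5
    consensual_gain: float = 1.0
    tau_rec_s: float = 0.5
    noise_sd_mm: float = 0.05
    lesion_direct_factor: float = 1.0
    lesion_speed_factor: float = 1.0
    rebound_frac: float = 0.0
    lesion_rebound_boost: float = 1.0

    def __post_init__(self) -> None:
        for name in ("baseline_right_mm", "baseline_left_mm"):
            b = getattr(self, name)
            if not 1.0 < b < 10.0:
                raise ModelError(f"{name}={b} outside (1, 10) mm")
        if not self.tau_fall_s > self.tau_rise_s > 0:
            raise ModelError(
                f"need tau_fall_s > tau_rise_s > 0, got "
                f"{self.tau_fall_s}, {self.tau_rise_s}"
            )
        if self.amplitude_mm < 0:
            raise ModelError("amplitude_mm must be non-negative")
        if self.amplitude_mm >= min(self.baseline_right_mm, self.baseline_left_mm):
            raise ModelError("amplitude_mm must be below both baselines")
        if self.consensual_gain < 0:
            raise ModelError("consensual_gain must be >= 0")
        if self.latency_s < 0 or self.tau_rec_s <= 0 or self.noise_sd_mm < 0:
            raise ModelError("latency_s >= 0, tau_rec_s > 0, noise_sd_mm >= 0 required")

    def baseline(self, eye: Eye | str) -> float:
        return (
            self.baseline_right_mm
            if Eye(eye) is Eye.RIGHT
            else self.baseline_left_mm
        )


@dataclass(frozen=True)
class Subject:
    """Cohort member with generator ground-truth parameters."""

    id: str
    age_years: float
    sex: str
    group: str  # "healthy" | "patient"
    lesion_side: str  # "none" | "left" | "right"
    params: PLRParameters

    def __post_init__(self) -> None:
        if self.group == "patient" and self.lesion_side == "none":
            raise ModelError(f"subject {self.id}: patients need a lesion side")
        if self.group == "healthy" and self.lesion_side != "none":
            raise ModelError(f"subject {self.id}: healthy subjects have no lesion")


def peak_time(tau_fall_s: float, tau_rise_s: float) -> float:
    """Time from constriction onset (post latency) to the waveform maximum."""
    if tau_fall_s <= tau_rise_s:
        raise ModelError("tau_fall_s must exceed tau_rise_s")
    return (
        tau_fall_s * tau_rise_s / (tau_fall_s - tau_rise_s)
    ) * math.log(tau_fall_s / tau_rise_s)


def _diffexp(s: np.ndarray, tau_fall: float, tau_rise: float) -> np.ndarray:
    s = np.maximum(s, 0.0)
    return np.exp(-s / tau_fall) - np.exp(-s / tau_rise)


def constriction_waveform(
    t_since_onset: float | np.ndarray, params: PLRParameters
) -> float | np.ndarray:
    """Constriction (mm) at time ``t_since_onset`` after stimulus onset.

    Zero before the latency, exactly ``amplitude_mm`` at the peak,
    continuous throughout.
    """
    if params.tau_fall_s == params.tau_rise_s:  # pragma: no cover - dataclass rejects
        raise ModelError("degenerate tau_fall == tau_rise")
    t = np.asarray(t_since_onset, dtype=float)
    if np.any(t < 0):
        raise ModelError("t_since_onset must be >= 0")
    s = t - params.latency_s
    norm = _diffexp(
        np.asarray(peak_time(params.tau_fall_s, params.tau_rise_s)),
        params.tau_fall_s,
        params.tau_rise_s,
    )
    out = np.where(
        s <= 0, 0.0, params.amplitude_mm * _diffexp(s, params.tau_fall_s, params.tau_rise_s) / norm
    )
    return float(out) if np.isscalar(t_since_onset) else out


def _rebound_shape(t: np.ndarray) -> np.ndarray:
    """Normalised rebound waveform (peak 1) as a function of recovery time."""
    norm = _diffexp(
        np.asarray(peak_time(REBOUND_TAU_FALL_S, REBOUND_TAU_RISE_S)),
        REBOUND_TAU_FALL_S,
        REBOUND_TAU_RISE_S,
    )
    return np.where(t <= 0, 0.0, _diffexp(t, REBOUND_TAU_FALL_S, REBOUND_TAU_RISE_S) / norm)


def _eye_params(subject: Subject, eye: Eye, stimulated: Eye) -> tuple[float, float, float]:
    """(amplitude, tau_fall, tau_rise) for one eye's response to one stimulus."""
    p = subject.params
    gain = 1.0 if eye is stimulated else p.consensual_gain
    amp = p.amplitude_mm * gain
    tf, tr = p.tau_fall_s, p.tau_rise_s
    if subject.lesion_side == eye.value:
        tf *= p.lesion_speed_factor
        tr *= p.lesion_speed_factor
        if eye is stimulated:
            amp *= p.lesion_direct_factor
    return amp, tf, tr


def _window_response(
    t: np.ndarray,
    window: StimulusWindow,
    amp: float,
    tau_fall: float,
    tau_rise: float,
    latency: float,
    tau_rec: float,
    rebound_mm: float,
) -> np.ndarray:
    """Diameter deficit (positive = constricted) contributed by one stimulus.

    Constriction follows the normalised difference of exponentials during
    the stimulus; during the latency after light-off the deficit is held at
    its offset value; afterwards it decays exponentially with ``tau_rec``
    while the rebound term transiently drives the deficit negative
    (dilation above resting).
    """
    if amp == 0.0 and rebound_mm == 0.0:
        return np.zeros_like(t)
    norm = float(_diffexp(np.asarray(peak_time(tau_fall, tau_rise)), tau_fall, tau_rise))
    onset, offset = window.onset_s, window.offset_s
    c = np.zeros_like(t)

    during = (t >= onset) & (t < offset + latency)
    s = np.minimum(t[during], offset) - onset - latency  # hold during post-offset latency
    c[during] = np.where(s <= 0, 0.0, amp * _diffexp(s, tau_fall, tau_rise) / norm)

    c_off = 0.0
    s_off = offset - onset - latency
    if s_off > 0:
        c_off = amp * float(_diffexp(np.asarray(s_off), tau_fall, tau_rise)) / norm

    after = t >= offset + latency
    tr_ = t[after] - offset - latency
    c[after] = c_off * np.exp(-tr_ / tau_rec) - rebound_mm * _rebound_shape(tr_)
    return c


def noiseless_diameters(
    subject: Subject, timeline: ProtocolTimeline, time_s: np.ndarray
) -> dict[Eye, np.ndarray]:
    """Deterministic model diameters for both eyes at the given times."""
    p = subject.params
    windows = stimulus_windows(timeline)
    out: dict[Eye, np.ndarray] = {}
    for eye in (Eye.RIGHT, Eye.LEFT):
        d = np.full_like(np.asarray(time_s, dtype=float), p.baseline(eye))
        for w in windows:
            amp, tf, tr = _eye_params(subject, eye, w.stimulated_eye)
            rebound = p.rebound_frac * p.baseline(eye)
            if subject.lesion_side == eye.value and eye is w.stimulated_eye:
                rebound *= p.lesion_rebound_boost
            d -= _window_response(
                np.asarray(time_s, dtype=float),
                w,
                amp,
                tf,
                tr,
                p.latency_s,
                p.tau_rec_s,
                rebound,
            )
        out[eye] = d
    return out


def _scan_window(values: np.ndarray, sel: np.ndarray):
    """(min, argmin_time_index) over a boolean selection; assumes sel nonempty."""
    idx = np.flatnonzero(sel)
    vals = values[idx]
    k = int(np.argmin(vals))
    return float(vals[k]), int(idx[k])


def _ground_truth(
    subject: Subject,
    timeline: ProtocolTimeline,
    time_s: np.ndarray,
    diameters: dict[Eye, np.ndarray],
) -> list["ReflexMeasurement"]:
    """Noiseless metric values scanned on the sampling grid."""
    from .metrics import ReflexMeasurement  # local import to avoid a cycle

    out = []
    for w in stimulus_windows(timeline):
        for eye in (Eye.RIGHT, Eye.LEFT):
            d = diameters[eye]
            stim = (time_s >= w.onset_s) & (time_s < w.offset_s)
            base = (time_s >= w.baseline_window[0]) & (time_s < w.baseline_window[1])
            rec = (time_s >= w.recovery_window[0]) & (time_s < w.recovery_window[1])
            min_mm, min_idx = _scan_window(d, stim)
            baseline_max = float(np.max(d[base]))
            recovery_max = float(np.max(d[rec]))
            out.append(
                ReflexMeasurement(
                    eye=eye,
                    stimulated_eye=w.stimulated_eye,
                    mode=classify_mode(eye, w.stimulated_eye),
                    baseline_max_mm=baseline_max,
                    min_mm=min_mm,
                    min_time_s=float(time_s[min_idx]),
                    miosis_rate=min_mm / baseline_max,
                    miosis_time_s=float(time_s[min_idx]) - w.onset_s,
                    recovery_max_mm=recovery_max,
                    mydriasis_rate=min_mm / recovery_max,
                )
            )
    return out


def simulate_trace(
    subject: Subject,
    timeline: ProtocolTimeline,
    sample_rate_hz: float = 60.0,
    seed: int | None = 0,
):
    """Simulate one session.

    Returns
    -------
    (PupilTrace, list[ReflexMeasurement])
        The sampled noisy trace and the noiseless ground-truth metrics
        (scanned on the same sampling grid, so a noiseless trace reproduces
        them exactly).

    Raises
    ------
    ModelError
        If the sample rate cannot resolve the shortest phase
        (``sample_rate_hz <= 2 / shortest_phase_duration``).
    """
    shortest = min(p.duration_s for p in timeline.phases)
    if sample_rate_hz <= 2.0 / shortest:
        raise ModelError(
            f"sample_rate_hz={sample_rate_hz} undersamples phases of {shortest} s"
        )
    n = int(round(timeline.total_s * sample_rate_hz))
    time_s = np.arange(n) / sample_rate_hz
    clean = noiseless_diameters(subject, timeline, time_s)
    truth = _ground_truth(subject, timeline, time_s, clean)

    rng = np.random.default_rng(seed)
    p = subject.params
    right = clean[Eye.RIGHT] + rng.normal(0.0, p.noise_sd_mm, n)
    left = clean[Eye.LEFT] + rng.normal(0.0, p.noise_sd_mm, n)
    trace = PupilTrace(
        sample_rate_hz=sample_rate_hz,
        time_s=time_s,
        right_mm=right,
        left_mm=left,
        illumination=illumination_labels(timeline, time_s),
        quality=np.array([QUALITY_OK] * n, dtype=object),
    )
    return trace, truth


def add_blink_artifacts(
    trace: PupilTrace,
    rate_per_s: float,
    duration_s: float,
    seed: int | None = 0,
) -> PupilTrace:
    """Flag randomly placed blink intervals and blank their diameters.

    Blink onsets are drawn from a Poisson process of ``rate_per_s``; each
    blink masks ``duration_s`` of consecutive samples.  ``ok`` samples
    outside blinks are untouched.
    """
    if rate_per_s < 0:
        raise ModelError("rate_per_s must be >= 0")
    session_len = trace.time_s[-1] - trace.time_s[0] + 1.0 / trace.sample_rate_hz
    if duration_s >= session_len:
        raise ModelError("blink duration_s must be shorter than the session")
    out = trace.copy()
    if rate_per_s == 0:
        return out
    rng = np.random.default_rng(seed)
    n_blinks = rng.poisson(rate_per_s * session_len)
    n_mask = max(1, int(round(duration_s * trace.sample_rate_hz)))
    for start_t in rng.uniform(trace.time_s[0], trace.time_s[-1], size=n_blinks):
        i0 = int(np.searchsorted(trace.time_s, start_t))
        sl = slice(i0, min(i0 + n_mask, len(trace)))
        out.quality[sl] = QUALITY_BLINK
        out.right_mm[sl] = np.nan
        out.left_mm[sl] = np.nan
    return out
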