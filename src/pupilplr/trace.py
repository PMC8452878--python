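"""Sampled bilateral pupil-diameter time series."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .protocol import Illumination, ProtocolTimeline

QUALITY_OK = "ok"
QUALITY_BLINK = "blink"
QUALITY_MISSING = "missing"
_QUALITIES = {QUALITY_OK, QUALITY_BLINK, QUALITY_MISSING}

#: Physiologically plausible diameter band for usable samples, mm.
DIAMETER_RANGE_MM = (0.5, 12.0)


class TraceError(ValueError):
    """Raised for inconsistent trace data."""


@dataclass
class PupilTrace:
    """Bilateral diameter series with per-sample illumination and quality.

    All arrays share one length.  Diameters are in millimetres; samples
    whose quality is not ``ok`` may be NaN.  ``illumination`` holds the
    protocol phase label active at each sample time.
    """

    sample_rate_hz: float
    time_s: np.ndarray
    right_mm: np.ndarray
    left_mm: np.ndarray
    illumination: np.ndarray  # array of str, values of Illumination
    quality: np.ndarray  # array of str in {ok, blink, missing}

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.right_mm = np.asarray(self.right_mm, dtype=float)
        self.left_mm = np.asarray(self.left_mm, dtype=float)
        self.illumination = np.asarray(self.illumination, dtype=object)
        self.quality = np.asarray(self.quality, dtype=object)
        n = len(self.time_s)
        for name in ("right_mm", "left_mm", "illumination", "quality"):
            if len(getattr(self, name)) != n:
                raise TraceError(f"{name} length differs from time_s")
        if n > 1 and not np.all(np.diff(self.time_s) > 0):
            bad = int(np.flatnonzero(np.diff(self.time_s) <= 0)[0]) + 1
            raise TraceError(f"time_s not strictly increasing at sample {bad}")
        unknown = set(self.quality) - _QUALITIES
        if unknown:
            raise TraceError(f"unknown quality flags: {sorted(unknown)}")
        bad_ill = {v for v in self.illumination} - {i.value for i in Illumination}
        if bad_ill:
            raise TraceError(f"unknown illumination labels: {sorted(bad_ill)}")
        ok = self.quality == QUALITY_OK
        lo, hi = DIAMETER_RANGE_MM
        for name, series in (("right_mm", self.right_mm), ("left_mm", self.left_mm)):
            vals = series[ok]
            if np.any(~np.isfinite(vals)) or np.any((vals <= lo) | (vals >= hi)):
                raise TraceError(
                    f"{name}: ok samples must be finite and within ({lo}, {hi}) mm"
                )

    def __len__(self) -> int:
        return len(self.time_s)

    def eye(self, eye) -> np.ndarray:
        from .protocol import Eye

        return self.right_mm if Eye(eye) is Eye.RIGHT else self.left_mm

    def ok_mask(self) -> np.ndarray:
        return self.quality == QUALITY_OK

    def copy(self) -> "PupilTrace":
        return PupilTrace(
            self.sample_rate_hz,
            self.time_s.copy(),
            self.right_mm.copy(),
            self.left_mm.copy(),
            self.illumination.copy(),
            self.quality.copy(),
        )


def illumination_labels(timeline: ProtocolTimeline, time_s: np.ndarray) -> np.ndarray:
    """Phase label active at each sample time (phases half-open [start, end))."""
    time_s = np.asarray(time_s, dtype=float)
    out = np.empty(len(time_s), dtype=object)
    out[:] = None
    for phase in timeline.phases:
        sel = (time_s >= phase.start_s) & (time_s < phase.end_s)
        out[sel] = phase.illumination.value
    if any(v is None for v in out):
        raise TraceError("sample times fall outside the session timeline")
    return out
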