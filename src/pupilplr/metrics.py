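"""The three pupillary light reflex statistics.

For one eye and one stimulus window:

* **miosis rate** — minimum diameter during irradiation divided by the
  maximum diameter in the immediately preceding infrared baseline phase;
* **miosis time** — seconds from stimulus onset to the earliest sample
  attaining the window minimum;
* **mydriasis rate** — minimum diameter during irradiation divided by the
  maximum diameter within 2 s after light-off.

Ratios are kept as plain ratios internally; multiply by 100 only at the
reporting layer.  All windows map to samples half-open [start, end).
Samples flagged blink/missing are excluded; a window with fewer than 25%
usable samples is treated as failed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .protocol import Eye, Mode, ProtocolTimeline, StimulusWindow, classify_mode, stimulus_windows
from .trace import PupilTrace

#: A window is usable only if at least this fraction of its samples are ok.
MIN_OK_FRACTION = 0.25


class WindowDataError(ValueError):
    """Raised when a window lacks enough usable samples."""


@dataclass(frozen=True)
class ReflexMeasurement:
    """One eye x one stimulus: the three metrics plus their ingredients."""

    eye: Eye
    stimulated_eye: Eye
    mode: Mode
    baseline_max_mm: float
    min_mm: float
    min_time_s: float  # absolute session time of the minimum
    miosis_rate: float
    miosis_time_s: float  # relative to stimulus onset
    recovery_max_mm: float
    mydriasis_rate: float

    def as_row(self) -> dict:
        return {
            "eye": self.eye.value,
            "stimulated_eye": self.stimulated_eye.value,
            "mode": self.mode.value,
            "baseline_max_mm": self.baseline_max_mm,
            "min_mm": self.min_mm,
            "miosis_rate": self.miosis_rate,
            "miosis_time_s": self.miosis_time_s,
            "recovery_max_mm": self.recovery_max_mm,
            "mydriasis_rate": self.mydriasis_rate,
            "miosis_rate_pct": 100.0 * self.miosis_rate,
            "mydriasis_rate_pct": 100.0 * self.mydriasis_rate,
        }


def _window_values(
    trace: PupilTrace, eye: Eye | str, start_s: float, end_s: float, label: str
):
    """(values, times) of usable samples in [start_s, end_s)."""
    sel = (trace.time_s >= start_s) & (trace.time_s < end_s)
    n_total = int(np.count_nonzero(sel))
    if n_total == 0:
        raise WindowDataError(f"{label} window [{start_s}, {end_s}) contains no samples")
    ok = sel & trace.ok_mask()
    n_ok = int(np.count_nonzero(ok))
    if n_ok == 0 or n_ok < MIN_OK_FRACTION * n_total:
        raise WindowDataError(
            f"{label} window [{start_s}, {end_s}): only {n_ok}/{n_total} usable samples"
        )
    return trace.eye(eye)[ok], trace.time_s[ok]


def miosis_rate(trace: PupilTrace, eye: Eye | str, window: StimulusWindow) -> float:
    """Minimum during irradiation over maximum in the preceding baseline."""
    stim_vals, _ = _window_values(trace, eye, window.onset_s, window.offset_s, "stimulus")
    base_vals, _ = _window_values(trace, eye, *window.baseline_window, "baseline")
    return float(np.min(stim_vals) / np.max(base_vals))


def miosis_time(trace: PupilTrace, eye: Eye | str, window: StimulusWindow) -> float:
    """Seconds from onset to the earliest usable sample attaining the minimum."""
    stim_vals, stim_times = _window_values(
        trace, eye, window.onset_s, window.offset_s, "stimulus"
    )
    return float(stim_times[int(np.argmin(stim_vals))] - window.onset_s)


def mydriasis_rate(trace: PupilTrace, eye: Eye | str, window: StimulusWindow) -> float:
    """Minimum during irradiation over maximum in the 2-s recovery window."""
    stim_vals, _ = _window_values(trace, eye, window.onset_s, window.offset_s, "stimulus")
    rec_vals, _ = _window_values(trace, eye, *window.recovery_window, "recovery")
    return float(np.min(stim_vals) / np.max(rec_vals))


def compute_session_metrics(
    trace: PupilTrace, timeline: ProtocolTimeline
) -> list[ReflexMeasurement]:
    """All (stimulus window x eye) measurements of one session, in order.

    Raises WindowDataError annotated with the failing eye and stimulus.
    """
    out = []
    for w in stimulus_windows(timeline):
        for eye in (Eye.RIGHT, Eye.LEFT):
            try:
                stim_vals, stim_times = _window_values(
                    trace, eye, w.onset_s, w.offset_s, "stimulus"
                )
                base_vals, _ = _window_values(trace, eye, *w.baseline_window, "baseline")
                rec_vals, _ = _window_values(trace, eye, *w.recovery_window, "recovery")
            except WindowDataError as err:
                raise WindowDataError(
                    f"{eye.value} eye, {w.stimulated_eye.value}-eye stimulus: {err}"
                ) from err
            k = int(np.argmin(stim_vals))
            min_mm = float(stim_vals[k])
            baseline_max = float(np.max(base_vals))
            recovery_max = float(np.max(rec_vals))
            out.append(
                ReflexMeasurement(
                    eye=eye,
                    stimulated_eye=w.stimulated_eye,
                    mode=classify_mode(eye, w.stimulated_eye),
                    baseline_max_mm=baseline_max,
                    min_mm=min_mm,
                    min_time_s=float(stim_times[k]),
                    miosis_rate=min_mm / baseline_max,
                    miosis_time_s=float(stim_times[k]) - w.onset_s,
                    recovery_max_mm=recovery_max,
                    mydriasis_rate=min_mm / recovery_max,
                )
            )
    return out


def spontaneous_diameters(trace: PupilTrace, timeline: ProtocolTimeline) -> dict[str, float]:
    """Per-eye spontaneous diameter: maximum in the first infrared phase."""
    first = timeline.phases[0]
    out = {}
    for eye in (Eye.RIGHT, Eye.LEFT):
        vals, _ = _window_values(trace, eye, first.start_s, first.end_s, "spontaneous")
        out[eye.value] = float(np.max(vals))
    return out


def metrics_table(
    per_subject: Sequence[tuple[str, Sequence[ReflexMeasurement]]]
) -> pd.DataFrame:
    """Long-format table: one row per subject x stimulus x eye."""
    rows = []
    for subject_id, measurements in per_subject:
        for m in measurements:
            row = {"subject_id": subject_id}
            row.update(m.as_row())
            rows.append(row)
    return pd.DataFrame(rows)


def write_metrics_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
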