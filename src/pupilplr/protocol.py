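"""Irradiation protocol of one binocular pupillometry session.

A session is a fixed sequence of illumination phases. The default session
lasts 10 s: infrared to both eyes (2 s), visible light to the right eye
(2 s), infrared (2 s), visible light to the left eye (2 s), infrared (2 s).
Infrared phases serve as measurement-only baselines; each visible-light
phase is a stimulus whose response is read on both pupils (direct on the
stimulated eye, indirect/consensual on the other).

Time is measured in seconds from session start.  When phases or analysis
windows are mapped onto discrete samples, intervals are half-open
``[start, end)`` so no boundary sample is counted twice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence


class Illumination(str, Enum):
    """Illumination state of one protocol phase."""

    IR_BOTH = "IR_BOTH"
    VIS_RIGHT = "VIS_RIGHT"
    VIS_LEFT = "VIS_LEFT"


class Eye(str, Enum):
    RIGHT = "right"
    LEFT = "left"


class Mode(str, Enum):
    DIRECT = "direct"
    INDIRECT = "indirect"


#: Duration of the post-stimulus recovery window used by the mydriasis rate,
#: "until 2 s after discontinuation of light irradiation".
RECOVERY_WINDOW_S = 2.0

_VIS_EYE = {Illumination.VIS_RIGHT: Eye.RIGHT, Illumination.VIS_LEFT: Eye.LEFT}


class ProtocolError(ValueError):
    """Raised for malformed timelines or windows."""


@dataclass(frozen=True)
class ProtocolPhase:
    """One contiguous illumination phase.

    Parameters
    ----------
    index : int
        1-based position of the phase within the session.
    start_s, end_s : float
        Phase boundaries in seconds from session start; ``end_s > start_s``.
    illumination : Illumination
        Light state during the phase.
    """

    index: int
    start_s: float
    end_s: float
    illumination: Illumination

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ProtocolError(f"phase index must be 1-based, got {self.index}")
        if not self.end_s > self.start_s:
            raise ProtocolError(
                f"phase {self.index}: end_s ({self.end_s}) must exceed start_s ({self.start_s})"
            )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class ProtocolTimeline:
    """Ordered, contiguous phases of one session."""

    phases: tuple[ProtocolPhase, ...]
    total_s: float = field(default=0.0)

    def __post_init__(self) -> None:
        if not self.phases:
            raise ProtocolError("timeline needs at least one phase")
        if self.phases[0].start_s != 0.0:
            raise ProtocolError("first phase must start at 0 s")
        for prev, cur in zip(self.phases, self.phases[1:]):
            if cur.start_s != prev.end_s:
                raise ProtocolError(
                    f"phases {prev.index} and {cur.index} are not contiguous"
                )
        object.__setattr__(self, "total_s", self.phases[-1].end_s)

    @property
    def vis_phases(self) -> tuple[ProtocolPhase, ...]:
        return tuple(p for p in self.phases if p.illumination is not Illumination.IR_BOTH)

    def to_config(self) -> list[dict]:
        """Serializable form: ordered ``{illumination, duration_s}`` entries."""
        return [
            {"illumination": p.illumination.value, "duration_s": p.duration_s}
            for p in self.phases
        ]

    @classmethod
    def from_config(cls, entries: Iterable[dict]) -> "ProtocolTimeline":
        phases = []
        t = 0.0
        for i, entry in enumerate(entries, start=1):
            dur = float(entry["duration_s"])
            if dur <= 0:
                raise ProtocolError(f"phase {i}: non-positive duration {dur}")
            phases.append(
                ProtocolPhase(i, t, t + dur, Illumination(entry["illumination"]))
            )
            t += dur
        return cls(tuple(phases))


@dataclass(frozen=True)
class StimulusWindow:
    """Analysis windows attached to one visible-light stimulus.

    ``baseline_window`` is the infrared phase immediately preceding the
    stimulus ("the maximum pupil diameter before light irradiation");
    ``recovery_window`` covers the 2 s after light-off, clipped to the
    session end.
    """

    stimulated_eye: Eye
    onset_s: float
    offset_s: float
    baseline_window: tuple[float, float]
    recovery_window: tuple[float, float]

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


def build_default_timeline() -> ProtocolTimeline:
    """The frozen default session: five 2-s phases, 10 s in total.

    Sequence IR_BOTH, VIS_RIGHT, IR_BOTH, VIS_LEFT, IR_BOTH, with phase
    starts at 0, 2, 4, 6 and 8 s.
    """
    order = [
        Illumination.IR_BOTH,
        Illumination.VIS_RIGHT,
        Illumination.IR_BOTH,
        Illumination.VIS_LEFT,
        Illumination.IR_BOTH,
    ]
    return ProtocolTimeline.from_config(
        [{"illumination": ill.value, "duration_s": 2.0} for ill in order]
    )


def stimulus_windows(timeline: ProtocolTimeline) -> list[StimulusWindow]:
    """One StimulusWindow per visible-light phase, in protocol order.

    Raises
    ------
    ProtocolError
        If a visible phase has no immediately preceding infrared baseline.
    """
    windows: list[StimulusWindow] = []
    phases = timeline.phases
    for i, phase in enumerate(phases):
        if phase.illumination is Illumination.IR_BOTH:
            continue
        if i == 0 or phases[i - 1].illumination is not Illumination.IR_BOTH:
            raise ProtocolError(
                f"stimulus phase {phase.index} lacks a preceding infrared baseline"
            )
        prev = phases[i - 1]
        rec_end = min(phase.end_s + RECOVERY_WINDOW_S, timeline.total_s)
        windows.append(
            StimulusWindow(
                stimulated_eye=_VIS_EYE[phase.illumination],
                onset_s=phase.start_s,
                offset_s=phase.end_s,
                baseline_window=(prev.start_s, prev.end_s),
                recovery_window=(phase.end_s, rec_end),
            )
        )
    return windows


def classify_mode(measured_eye: Eye | str, stimulated_eye: Eye | str) -> Mode:
    """Direct if the measured eye is the stimulated one, else indirect."""
    return Mode.DIRECT if Eye(measured_eye) is Eye(stimulated_eye) else Mode.INDIRECT
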