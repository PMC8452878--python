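"""Synthetic healthy and patient cohorts.

Healthy cohort
--------------
Twenty-five volunteers, five per age bracket.  Resting diameter declines
linearly with age (senile miosis), the right pupil exceeds the left by a
fixed anisocoria offset, and the relative constriction amplitude declines
with age so that miosis becomes weaker (rates closer to 1) in older
subjects.  All per-subject variation is seed-reproducible.

Patient cohort
--------------
Five intensive-care patients with left-sided intracranial lesions, ages
fixed to the study roster (75, 86, 72, 47, 89).  Relative to healthy
defaults the lesioned (left) eye constricts less under direct stimulation
and runs on faster time constants in both modes, and both eyes show a
transient post-stimulus rebound above the resting diameter, which lowers
mydriasis rates bilaterally.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .plr_model import ModelError, PLRParameters, Subject

#: Default age brackets (years, half-open).  Five brackets of five subjects
#: spanning ages 20-91; bracket midpoints average 47.2 years.
DEFAULT_AGE_BRACKETS: tuple[tuple[float, float], ...] = (
    (20.0, 30.0),
    (30.0, 40.0),
    (40.0, 50.0),
    (50.0, 60.0),
    (60.0, 92.0),
)

#: Fixed patient roster: (age, sex).  All lesions are left-sided.
PATIENT_ROSTER: tuple[tuple[int, str], ...] = (
    (75, "F"),
    (86, "M"),
    (72, "M"),
    (47, "F"),
    (89, "M"),
)


@dataclass(frozen=True)
class GeneratorDefaults:
    """Population-level generator parameters.

    Baseline model: resting diameter ``b0 - b1 * age`` mm plus N(0, subject_sd);
    the right eye sits ``anisocoria_mm`` above the left.  Relative
    constriction amplitude: ``amp0 - amp_slope * age`` of the mean resting
    diameter, plus N(0, amp_sd).
    """

    b0_mm: float = 6.5
    b1_mm_per_year: float = 0.035
    subject_sd_mm: float = 0.35
    anisocoria_mm: float = 0.7
    amp0: float = 0.40
    amp_slope_per_year: float = 0.0012
    amp_sd: float = 0.015
    latency_s: float = 0.2
    latency_sd_s: float = 0.015
    tau_fall_s: float = 1.4
    tau_rise_s: float = 0.3
    tau_rec_s: float = 0.5
    tau_jitter: float = 0.03  # multiplicative SD on time constants
    consensual_gain: float = 1.0
    noise_sd_mm: float = 0.05
    # patient-only effects
    patient_tau_rec_s: float = 0.4
    lesion_direct_factor: float = 0.7
    lesion_speed_factor: float = 0.6
    patient_rebound_frac: float = 0.12
    patient_lesion_rebound_boost: float = 2.5


DEFAULTS = GeneratorDefaults()


def _draw_params(
    age: float, rng: np.random.Generator, g: GeneratorDefaults
) -> PLRParameters:
    mean_b = g.b0_mm - g.b1_mm_per_year * age + rng.normal(0.0, g.subject_sd_mm)
    mean_b = float(np.clip(mean_b, 1.8, 9.0))
    amp_frac = g.amp0 - g.amp_slope_per_year * age + rng.normal(0.0, g.amp_sd)
    amp_frac = float(np.clip(amp_frac, 0.10, 0.60))
    jitter = np.exp(rng.normal(0.0, g.tau_jitter, size=3))
    latency = max(0.05, g.latency_s + rng.normal(0.0, g.latency_sd_s))
    return PLRParameters(
        baseline_right_mm=mean_b + g.anisocoria_mm / 2.0,
        baseline_left_mm=mean_b - g.anisocoria_mm / 2.0,
        latency_s=latency,
        tau_fall_s=g.tau_fall_s * float(jitter[0]),
        tau_rise_s=g.tau_rise_s * float(jitter[1]),
        amplitude_mm=amp_frac * mean_b,
        consensual_gain=g.consensual_gain,
        tau_rec_s=g.tau_rec_s * float(jitter[2]),
        noise_sd_mm=g.noise_sd_mm,
    )


def generate_healthy_cohort(
    n: int = 25,
    seed: int | None = 0,
    defaults: GeneratorDefaults = DEFAULTS,
    age_brackets: Sequence[tuple[float, float]] = DEFAULT_AGE_BRACKETS,
) -> list[Subject]:
    """Healthy volunteers, ``n / len(age_brackets)`` per bracket.

    Ages are uniform within each bracket; the same (n, seed, defaults)
    always produces the identical cohort.
    """
    if n <= 0:
        raise ModelError("cohort size must be positive")
    if n % len(age_brackets) != 0:
        raise ModelError(
            f"n={n} not divisible by the {len(age_brackets)} age brackets"
        )
    per = n // len(age_brackets)
    rng = np.random.default_rng(seed)
    subjects = []
    for lo, hi in age_brackets:
        for _ in range(per):
            age = float(rng.uniform(lo, hi))
            sex = "M" if rng.random() < 0.6 else "F"
            subjects.append(
                Subject(
                    id=f"H{len(subjects) + 1:02d}",
                    age_years=age,
                    sex=sex,
                    group="healthy",
                    lesion_side="none",
                    params=_draw_params(age, rng, defaults),
                )
            )
    return subjects


def generate_patient_cohort(
    seed: int | None = 0, defaults: GeneratorDefaults = DEFAULTS
) -> list[Subject]:
    """Five left-lesion patients with the fixed study roster of ages."""
    rng = np.random.default_rng(seed)
    subjects = []
    for i, (age, sex) in enumerate(PATIENT_ROSTER, start=1):
        base = _draw_params(float(age), rng, defaults)
        params = replace(
            base,
            tau_rec_s=defaults.patient_tau_rec_s
            * float(np.exp(rng.normal(0.0, defaults.tau_jitter))),
            lesion_direct_factor=defaults.lesion_direct_factor,
            lesion_speed_factor=defaults.lesion_speed_factor,
            rebound_frac=defaults.patient_rebound_frac,
            lesion_rebound_boost=defaults.patient_lesion_rebound_boost,
        )
        subjects.append(
            Subject(
                id=f"P{i:02d}",
                age_years=float(age),
                sex=sex,
                group="patient",
                lesion_side="left",
                params=params,
            )
        )
    return subjects


def cohort_to_json(subjects: Sequence[Subject], path: str | Path) -> None:
    payload = []
    for s in subjects:
        d = asdict(s)
        d["params"] = asdict(s.params)
        payload.append(d)
    Path(path).write_text(json.dumps(payload, indent=1))


def cohort_from_json(path: str | Path) -> list[Subject]:
    payload = json.loads(Path(path).read_text())
    return [
        Subject(
            id=d["id"],
            age_years=d["age_years"],
            sex=d["sex"],
            group=d["group"],
            lesion_side=d["lesion_side"],
            params=PLRParameters(**d["params"]),
        )
        for d in payload
    ]
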