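#!/usr/bin/env python
"""Generate the default cohorts and example session traces.

Writes the two cohort rosters (with per-subject ground-truth parameters)
and one example simulated session per group under results/, and prints the
cohort design summary.
"""

from pathlib import Path

import numpy as np

from pupilplr.cohort import (
    cohort_to_json,
    generate_healthy_cohort,
    generate_patient_cohort,
)
from pupilplr.io import write_trace
from pupilplr.plr_model import simulate_trace
from pupilplr.protocol import build_default_timeline

SEED = 0
OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    timeline = build_default_timeline()
    healthy = generate_healthy_cohort(25, seed=SEED)
    patients = generate_patient_cohort(seed=SEED + 1)
    cohort_to_json(healthy, OUT / "healthy_cohort.json")
    cohort_to_json(patients, OUT / "patient_cohort.json")

    for subject, name in ((healthy[0], "example_healthy_trace.csv"),
                          (patients[0], "example_patient_trace.csv")):
        trace, _ = simulate_trace(subject, timeline, 60.0, seed=SEED)
        write_trace(trace, OUT / name)

    ages = np.array([s.age_years for s in healthy])
    print(f"healthy cohort: n={len(healthy)}, ages {ages.min():.0f}-{ages.max():.0f} "
          f"(mean {ages.mean():.1f}), over-60 subset n={np.sum(ages >= 60)}")
    aniso = np.mean([s.params.baseline_right_mm - s.params.baseline_left_mm for s in healthy])
    print(f"generator anisocoria (right - left resting diameter): {aniso:.2f} mm")
    print(f"patient cohort: n={len(patients)}, ages "
          f"{sorted(int(s.age_years) for s in patients)}, all lesions left")
    print(f"wrote rosters and example traces to {OUT}")


if __name__ == "__main__":
    main()
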