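#!/usr/bin/env python
"""Simulate one session per subject and tabulate the three reflex metrics.

Writes per-subject spontaneous diameters and the long-format metric table
(miosis rate, miosis time, mydriasis rate per eye x stimulus) for both
default cohorts under results/.
"""

from pathlib import Path

from pupilplr.cohort import generate_healthy_cohort, generate_patient_cohort
from pupilplr.protocol import build_default_timeline
from pupilplr.studies import simulate_cohort_sessions

SEED = 0
OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    timeline = build_default_timeline()
    for name, cohort, seed in (
        ("healthy", generate_healthy_cohort(25, seed=SEED), SEED),
        ("patient", generate_patient_cohort(seed=SEED + 1), SEED + 1),
    ):
        sp, metrics = simulate_cohort_sessions(cohort, timeline, 60.0, seed=seed)
        sp.to_csv(OUT / f"{name}_spontaneous.csv", index=False, float_format="%.5g")
        metrics.to_csv(OUT / f"{name}_metrics.tsv", sep="\t", index=False,
                       float_format="%.5g")
        print(f"{name}: {len(sp)} subjects, {len(metrics)} metric rows")
        summary = metrics.groupby(["eye", "stimulated_eye"])[
            ["miosis_rate", "miosis_time_s", "mydriasis_rate"]
        ].mean().round(3)
        print(summary.to_string(), "\n")
    print(f"wrote tables to {OUT}")


if __name__ == "__main__":
    main()
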