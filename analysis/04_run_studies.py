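#!/usr/bin/env python
"""Run the three cohort analyses and write the reports.

Study 1: right-vs-left spontaneous diameters and direct-vs-indirect
equivalence in the healthy cohort.  Study 2: age correlations.  Study 3:
over-60 healthy subset versus left-lesion patients with headline flags.
Writes results/study_report.{json,md}; column-scatter figures go under
scratch/figures (not part of the deliverable tables).
"""

import json
from pathlib import Path

from pupilplr.cohort import generate_healthy_cohort, generate_patient_cohort
from pupilplr.protocol import build_default_timeline
from pupilplr.studies import (
    plot_column_scatter,
    report_to_markdown,
    run_study1,
    run_study2,
    run_study3,
    simulate_cohort_sessions,
)

SEED = 0
ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "results"
FIG = ROOT / "scratch" / "figures"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    timeline = build_default_timeline()
    h_sp, h_m = simulate_cohort_sessions(
        generate_healthy_cohort(25, seed=SEED), timeline, 60.0, seed=SEED
    )
    p_sp, p_m = simulate_cohort_sessions(
        generate_patient_cohort(seed=SEED + 1), timeline, 60.0, seed=SEED + 1
    )
    s1 = run_study1(h_sp, h_m)
    s2 = run_study2(h_sp, h_m)
    s3 = run_study3(h_sp, h_m, p_sp, p_m)

    (OUT / "study_report.json").write_text(json.dumps(
        {"study1": s1.as_dict(), "study2": s2.as_dict(), "study3": s3.as_dict(),
         "seed": SEED}, indent=1))
    (OUT / "study_report.md").write_text(report_to_markdown(s1, s2, s3))

    c = s1.right_vs_left_spontaneous
    print(f"study 1: spontaneous right {c.mean_a:.2f} mm vs left {c.mean_b:.2f} mm, "
          f"{c.test_used} p = {c.p_value:.2g}")
    print("study 1: pooled direct-vs-indirect p-values:",
          {x.metric_name: round(x.p_value, 3) for x in s1.direct_vs_indirect_pooled})
    print("study 2: age vs spontaneous diameter r:",
          {x.variable: round(x.r, 2) for x in s2.spontaneous})
    print("study 3 flags:", s3.flags)

    FIG.mkdir(parents=True, exist_ok=True)
    plot_column_scatter(
        {"right": h_sp["right_mm"], "left": h_sp["left_mm"]},
        "spontaneous diameter (mm)", FIG / "spontaneous_right_left.png",
    )
    h60 = h_m[h_m.subject_id.isin(s3.healthy_subset_ids)]
    cell = lambda df, e, s: df.query("eye == @e and stimulated_eye == @s")["mydriasis_rate"]
    plot_column_scatter(
        {"healthy": cell(h60, "left", "left"), "patient": cell(p_m, "left", "left")},
        "left-direct mydriasis rate", FIG / "study3_mydriasis_left_direct.png",
    )
    print(f"wrote {OUT / 'study_report.json'}, {OUT / 'study_report.md'}, figures in {FIG}")


if __name__ == "__main__":
    main()
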