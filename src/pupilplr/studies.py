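"""Cohort-level analyses: laterality, ageing, and patient comparison.

Three analyses run on per-subject session tables:

* **Study 1 (healthy laterality):** paired right-vs-left spontaneous
  diameters, and direct-vs-indirect comparisons of the three reflex
  metrics — per eye (as the condition is displayed) and pooled across
  eyes (the order-balanced contrast).
* **Study 2 (ageing):** Pearson correlations of age against spontaneous
  diameters and against each metric in every eye x stimulation cell.
* **Study 3 (patients):** the over-60 healthy subset versus the left-lesion
  patients, on spontaneous diameters and every metric x condition cell,
  with directional headline flags for the lesion-side findings.

All tables are pandas DataFrames produced by :func:`simulate_cohort_sessions`
or assembled from measured traces with the same columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import GeneratorDefaults
from .metrics import compute_session_metrics, spontaneous_diameters
from .plr_model import Subject, simulate_trace
from .protocol import Eye, ProtocolTimeline
from .stats import (
    CorrelationResult,
    GroupComparison,
    StatsError,
    compare_groups,
    compare_paired,
    correlate_with_age,
)

METRIC_NAMES = ("miosis_rate", "miosis_time_s", "mydriasis_rate")


def _subject_seed(seed: int, i: int) -> int:
    return (seed * 100003 + 7919 * i + 1) % (2**31 - 1)


def simulate_cohort_sessions(
    cohort: Sequence[Subject],
    timeline: ProtocolTimeline,
    sample_rate_hz: float = 60.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one session per subject and tabulate the pipeline outputs.

    Returns
    -------
    (spontaneous, metrics)
        ``spontaneous``: one row per subject with right/left spontaneous
        diameters (max in the first infrared phase).  ``metrics``: one row
        per subject x stimulus x eye with the three reflex metrics.
    """
    sp_rows, m_rows = [], []
    for i, subject in enumerate(cohort):
        trace, _ = simulate_trace(
            subject, timeline, sample_rate_hz, seed=_subject_seed(seed, i)
        )
        sp = spontaneous_diameters(trace, timeline)
        sp_rows.append(
            {
                "subject_id": subject.id,
                "age_years": subject.age_years,
                "group": subject.group,
                "right_mm": sp["right"],
                "left_mm": sp["left"],
            }
        )
        for m in compute_session_metrics(trace, timeline):
            row = {
                "subject_id": subject.id,
                "age_years": subject.age_years,
                "group": subject.group,
            }
            row.update(m.as_row())
            m_rows.append(row)
    return pd.DataFrame(sp_rows), pd.DataFrame(m_rows)


def _cell(metrics: pd.DataFrame, eye: str, stimulated_eye: str) -> pd.DataFrame:
    sel = (metrics["eye"] == eye) & (metrics["stimulated_eye"] == stimulated_eye)
    return metrics.loc[sel].sort_values("subject_id")


@dataclass
class Study1Report:
    right_vs_left_spontaneous: GroupComparison
    direct_vs_indirect_by_eye: list[GroupComparison]
    direct_vs_indirect_pooled: list[GroupComparison]
    n_tests: int = 0

    def __post_init__(self) -> None:
        self.n_tests = 1 + len(self.direct_vs_indirect_by_eye) + len(
            self.direct_vs_indirect_pooled
        )

    def as_dict(self) -> dict:
        return {
            "right_vs_left_spontaneous": self.right_vs_left_spontaneous.as_dict(),
            "direct_vs_indirect_by_eye": [c.as_dict() for c in self.direct_vs_indirect_by_eye],
            "direct_vs_indirect_pooled": [c.as_dict() for c in self.direct_vs_indirect_pooled],
            "n_tests": self.n_tests,
        }


def run_study1(
    spontaneous: pd.DataFrame,
    metrics: pd.DataFrame,
    alpha_normality: float = 0.05,
) -> Study1Report:
    """Healthy laterality and direct-vs-indirect equivalence."""
    sp = spontaneous.dropna(subset=["right_mm", "left_mm"])
    if len(sp) < 2:
        raise StatsError("study 1 needs spontaneous diameters for >= 2 subjects")
    paired = compare_paired(
        sp["right_mm"], sp["left_mm"], alpha_normality,
        metric_name="spontaneous_mm", condition="right_vs_left",
    )
    by_eye, pooled = [], []
    for name in METRIC_NAMES:
        for eye in ("right", "left"):
            direct = metrics.query("eye == @eye and mode == 'direct'")[name]
            indirect = metrics.query("eye == @eye and mode == 'indirect'")[name]
            by_eye.append(
                compare_groups(
                    direct, indirect, alpha_normality,
                    metric_name=name, condition=f"{eye}:direct_vs_indirect",
                )
            )
        pooled.append(
            compare_groups(
                metrics.query("mode == 'direct'")[name],
                metrics.query("mode == 'indirect'")[name],
                alpha_normality,
                metric_name=name,
                condition="pooled:direct_vs_indirect",
            )
        )
    return Study1Report(paired, by_eye, pooled)


@dataclass
class Study2Report:
    spontaneous: list[CorrelationResult]
    metric_correlations: list[CorrelationResult]
    n_tests: int = 0

    def __post_init__(self) -> None:
        self.n_tests = len(self.spontaneous) + len(self.metric_correlations)

    def as_dict(self) -> dict:
        return {
            "spontaneous": [c.as_dict() for c in self.spontaneous],
            "metric_correlations": [c.as_dict() for c in self.metric_correlations],
            "n_tests": self.n_tests,
        }


def run_study2(spontaneous: pd.DataFrame, metrics: pd.DataFrame) -> Study2Report:
    """Age correlations: 2 spontaneous entries + 3 metrics x 4 cells."""
    sp_corr = [
        correlate_with_age(
            spontaneous[f"{eye}_mm"], spontaneous["age_years"],
            variable=f"spontaneous_{eye}_mm",
        )
        for eye in ("right", "left")
    ]
    m_corr = []
    for name in METRIC_NAMES:
        for stim in ("right", "left"):
            for eye in ("right", "left"):
                cell = _cell(metrics, eye, stim)
                m_corr.append(
                    correlate_with_age(
                        cell[name], cell["age_years"],
                        variable=f"{name}:{eye}_eye:{stim}_stim",
                    )
                )
    return Study2Report(sp_corr, m_corr)


@dataclass
class Study3Report:
    healthy_subset_ids: list[str]
    spontaneous: list[GroupComparison]
    metric_comparisons: list[GroupComparison]
    flags: dict = field(default_factory=dict)
    n_tests: int = 0

    def __post_init__(self) -> None:
        self.n_tests = len(self.spontaneous) + len(self.metric_comparisons)

    def comparison(self, metric: str, eye: str, stim: str) -> GroupComparison:
        cond = f"{eye}_eye:{stim}_stim"
        for c in self.metric_comparisons:
            if c.metric_name == metric and c.condition == cond:
                return c
        raise KeyError((metric, eye, stim))

    def as_dict(self) -> dict:
        return {
            "healthy_subset_ids": self.healthy_subset_ids,
            "spontaneous": [c.as_dict() for c in self.spontaneous],
            "metric_comparisons": [c.as_dict() for c in self.metric_comparisons],
            "flags": self.flags,
            "n_tests": self.n_tests,
        }


def run_study3(
    healthy_spontaneous: pd.DataFrame,
    healthy_metrics: pd.DataFrame,
    patient_spontaneous: pd.DataFrame,
    patient_metrics: pd.DataFrame,
    lesion_side: str = "left",
    age_cut_years: float = 60.0,
    alpha: float = 0.05,
    alpha_normality: float = 0.05,
) -> Study3Report:
    """Over-60 healthy subset versus patients, all metric x condition cells.

    Headline flags (each requires significance at ``alpha`` AND the
    direction): elevated lesion-side direct miosis rate; shortened
    lesion-side miosis times (both modes); exaggerated mydriasis (all four
    cells lower in patients).
    """
    subset = healthy_spontaneous.query("age_years >= @age_cut_years")
    if len(subset) < 5:
        raise StatsError(
            f"study 3 needs >= 5 healthy subjects over {age_cut_years}, got {len(subset)}"
        )
    ids = sorted(subset["subject_id"])
    h_metrics = healthy_metrics[healthy_metrics["subject_id"].isin(ids)]

    sp_cmp = [
        compare_groups(
            subset[f"{eye}_mm"], patient_spontaneous[f"{eye}_mm"], alpha_normality,
            metric_name=f"spontaneous_{eye}_mm", condition="healthy_vs_patient",
        )
        for eye in ("right", "left")
    ]
    m_cmp = []
    for name in METRIC_NAMES:
        for eye in ("right", "left"):
            for stim in ("right", "left"):
                m_cmp.append(
                    compare_groups(
                        _cell(h_metrics, eye, stim)[name],
                        _cell(patient_metrics, eye, stim)[name],
                        alpha_normality,
                        metric_name=name,
                        condition=f"{eye}_eye:{stim}_stim",
                    )
                )
    report = Study3Report(ids, sp_cmp, m_cmp)

    other = "right" if lesion_side == "left" else "left"
    c = report.comparison("miosis_rate", lesion_side, lesion_side)
    report.flags["lesion_direct_miosis_rate_elevated"] = bool(
        c.p_value < alpha and c.mean_b > c.mean_a
    )
    time_cells = [
        report.comparison("miosis_time_s", lesion_side, stim) for stim in ("right", "left")
    ]
    report.flags["lesion_side_miosis_time_shortened"] = bool(
        all(c.p_value < alpha and c.mean_b < c.mean_a for c in time_cells)
    )
    myd_cells = [
        report.comparison("mydriasis_rate", eye, stim)
        for eye in ("right", "left")
        for stim in ("right", "left")
    ]
    report.flags["mydriasis_exaggerated_bilaterally"] = bool(
        all(c.p_value < alpha and c.mean_b < c.mean_a for c in myd_cells)
    )
    return report


def report_to_markdown(study1: Study1Report, study2: Study2Report, study3: Study3Report) -> str:
    """Human-readable summary of all three analyses."""
    lines = ["# Cohort analyses", "", "## Study 1: laterality and direct vs indirect", ""]
    c = study1.right_vs_left_spontaneous
    lines += [
        f"Spontaneous diameter right vs left (paired, {c.test_used}): "
        f"mean R {c.mean_a:.2f} mm vs L {c.mean_b:.2f} mm, p = {c.p_value:.2g}",
        "",
        "| metric | condition | test | p |",
        "|---|---|---|---|",
    ]
    for cc in study1.direct_vs_indirect_by_eye + study1.direct_vs_indirect_pooled:
        lines.append(
            f"| {cc.metric_name} | {cc.condition} | {cc.test_used} | {cc.p_value:.2g} |"
        )
    lines += ["", "## Study 2: age correlations", "", "| variable | r | p | n |", "|---|---|---|---|"]
    for r in study2.spontaneous + study2.metric_correlations:
        lines.append(f"| {r.variable} | {r.r:.2f} | {r.p_value:.2g} | {r.n} |")
    lines += [
        "",
        "## Study 3: over-60 healthy vs left-lesion patients",
        "",
        f"Healthy subset: {', '.join(study3.healthy_subset_ids)}",
        "",
        "| metric | condition | healthy mean | patient mean | test | p |",
        "|---|---|---|---|---|---|",
    ]
    for cc in study3.spontaneous + study3.metric_comparisons:
        lines.append(
            f"| {cc.metric_name} | {cc.condition} | {cc.mean_a:.3f} | {cc.mean_b:.3f} "
            f"| {cc.test_used} | {cc.p_value:.2g} |"
        )
    lines += ["", "Flags: " + ", ".join(f"{k}={v}" for k, v in study3.flags.items()), ""]
    lines.append(f"Tests performed (no multiplicity correction): "
                 f"{study1.n_tests + study2.n_tests + study3.n_tests}")
    return "\n".join(lines)


def plot_column_scatter(groups: dict[str, Sequence[float]], ylabel: str, path) -> None:
    """Column scatter (one jittered column per group) with mean +/- SD bars."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rng = np.random.default_rng(0)
    fig, ax = plt.subplots(figsize=(1.2 * len(groups) + 1, 3.2))
    for i, (name, vals) in enumerate(groups.items()):
        vals = np.asarray(vals, dtype=float)
        x = i + rng.uniform(-0.12, 0.12, len(vals))
        ax.plot(x, vals, "o", ms=4, color="k", alpha=0.7)
        ax.errorbar(i, vals.mean(), yerr=vals.std(ddof=1), fmt="_", color="r",
                    capsize=8, elinewidth=1.5, markersize=18)
    ax.set_xticks(range(len(groups)), list(groups))
    ax.set_ylabel(ylabel)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
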