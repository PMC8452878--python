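"""Normality-gated two-sample comparison and age correlation.

The comparison rule follows the study's analysis plan: each sample is first
checked for normality with the Shapiro-Wilk test; if both pass at
``alpha_normality`` the groups are compared with Student's two-sample
t-test (equal variances), otherwise with the two-sided Mann-Whitney U-test.
A constant sample, for which Shapiro-Wilk is undefined, falls back to the
Mann-Whitney U-test and is flagged.  No multiple-testing correction is
applied; reports carry the count of tests performed instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

DEFAULT_NORMALITY_ALPHA = 0.05


class StatsError(ValueError):
    """Raised for inputs too small or degenerate to analyse."""


@dataclass(frozen=True)
class GroupComparison:
    """Outcome of one normality-gated two-group comparison."""

    metric_name: str
    condition: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    median_a: float
    median_b: float
    normality_p_a: float | None
    normality_p_b: float | None
    test_used: str  # "students_t" | "mann_whitney_u"
    statistic: float
    p_value: float
    normality_undefined: bool = False

    def as_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation of one variable against age."""

    variable: str
    r: float
    p_value: float
    n: int
    defined: bool = True

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _is_constant(x: np.ndarray) -> bool:
    return bool(np.ptp(x) == 0.0)


def compare_groups(
    a,
    b,
    alpha_normality: float = DEFAULT_NORMALITY_ALPHA,
    metric_name: str = "",
    condition: str = "",
) -> GroupComparison:
    """Compare two independent samples with the normality-gated rule.

    Both samples need at least 3 values.  Swapping ``a`` and ``b`` never
    changes the test chosen or the two-sided p-value.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise StatsError("each sample needs at least 3 values")
    if np.any(~np.isfinite(a)) or np.any(~np.isfinite(b)):
        raise StatsError("samples must be finite")

    undefined = _is_constant(a) or _is_constant(b)
    p_a = p_b = None
    if not undefined:
        p_a = float(sps.shapiro(a).pvalue)
        p_b = float(sps.shapiro(b).pvalue)

    if not undefined and p_a >= alpha_normality and p_b >= alpha_normality:
        test_used = "students_t"
        res = sps.ttest_ind(a, b, equal_var=True)
        statistic, p_value = float(res.statistic), float(res.pvalue)
        if math.isnan(p_value):  # both samples constant and equal
            statistic, p_value = 0.0, 1.0
    else:
        test_used = "mann_whitney_u"
        res = sps.mannwhitneyu(a, b, alternative="two-sided")
        statistic, p_value = float(res.statistic), float(res.pvalue)

    return GroupComparison(
        metric_name=metric_name,
        condition=condition,
        n_a=len(a),
        n_b=len(b),
        mean_a=float(np.mean(a)),
        mean_b=float(np.mean(b)),
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
        normality_p_a=p_a,
        normality_p_b=p_b,
        test_used=test_used,
        statistic=statistic,
        p_value=p_value,
        normality_undefined=undefined,
    )


def compare_paired(
    a,
    b,
    alpha_normality: float = DEFAULT_NORMALITY_ALPHA,
    metric_name: str = "",
    condition: str = "",
) -> GroupComparison:
    """Within-subject analogue of :func:`compare_groups`.

    Shapiro-Wilk is applied to the paired differences; a paired t-test is
    used when they pass, the Wilcoxon signed-rank test otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b):
        raise StatsError("paired samples must have equal length")
    if len(a) < 3:
        raise StatsError("need at least 3 pairs")
    diff = a - b
    undefined = _is_constant(diff)
    p_d = None if undefined else float(sps.shapiro(diff).pvalue)
    if not undefined and p_d >= alpha_normality:
        test_used = "paired_t"
        res = sps.ttest_rel(a, b)
        statistic, p_value = float(res.statistic), float(res.pvalue)
    elif np.all(diff == 0):
        test_used, statistic, p_value = "wilcoxon", 0.0, 1.0
    else:
        test_used = "wilcoxon"
        res = sps.wilcoxon(a, b, zero_method="wilcox")
        statistic, p_value = float(res.statistic), float(res.pvalue)
    return GroupComparison(
        metric_name=metric_name,
        condition=condition,
        n_a=len(a),
        n_b=len(b),
        mean_a=float(np.mean(a)),
        mean_b=float(np.mean(b)),
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
        normality_p_a=p_d,
        normality_p_b=p_d,
        test_used=test_used,
        statistic=statistic,
        p_value=p_value,
        normality_undefined=undefined,
    )


def correlate_with_age(values, ages, variable: str = "") -> CorrelationResult:
    """Pearson r (two-sided p) between a metric and age."""
    values = np.asarray(values, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if len(values) != len(ages):
        raise StatsError("values and ages must have equal length")
    if len(values) < 3:
        raise StatsError("need at least 3 observations")
    if _is_constant(values) or _is_constant(ages):
        return CorrelationResult(variable=variable, r=float("nan"), p_value=float("nan"), n=len(values), defined=False)
    res = sps.pearsonr(values, ages)
    return CorrelationResult(
        variable=variable, r=float(res.statistic), p_value=float(res.pvalue), n=len(values)
    )
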