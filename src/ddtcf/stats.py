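"""Descriptive and inferential statistics for cohort comparisons.

Thin, validated wrappers around scipy.stats exposing exactly the tests the
culture-monitoring analysis uses: five-number boxplot summaries, Welch's
unpaired t-test, one-way ANOVA with Tukey's honest-significant-difference
post-hoc, and Pearson correlation.  Quantiles use linear interpolation
between order statistics (R type 7), fixed here for reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np
from scipy import stats as _sps

from .errors import ValidationError

__all__ = [
    "FiveNumberSummary",
    "TestResult",
    "five_number_summary",
    "unpaired_t_test",
    "one_way_anova",
    "tukey_hsd",
    "pearson_correlation",
]


@dataclass(frozen=True)
class FiveNumberSummary:
    minimum: float
    q1: float
    median: float
    q3: float
    maximum: float

    def __post_init__(self) -> None:
        if not (self.minimum <= self.q1 <= self.median <= self.q3 <= self.maximum):
            raise ValidationError("five-number summary must be non-decreasing")

    def as_tuple(self) -> tuple[float, float, float, float, float]:
        return (self.minimum, self.q1, self.median, self.q3, self.maximum)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: Union[float, tuple[float, float]]
    p_value: float
    method: str
    group_labels: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValidationError(f"p_value must lie in [0, 1], got {self.p_value}")


def _as_array(values: Sequence[float], name: str, min_len: int = 1) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size < min_len:
        raise ValidationError(f"{name} must be a 1-d sequence of at least {min_len} values")
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} contains non-finite values")
    return arr


def five_number_summary(values: Sequence[float]) -> FiveNumberSummary:
    """Minimum, quartiles and maximum with linear-interpolation quantiles."""
    arr = _as_array(values, "values", min_len=1)
    q = np.quantile(arr, [0.0, 0.25, 0.5, 0.75, 1.0], method="linear")
    return FiveNumberSummary(*map(float, q))


def unpaired_t_test(group_a: Sequence[float], group_b: Sequence[float]) -> TestResult:
    """Welch's two-sided unpaired t-test (unequal variances)."""
    a = _as_array(group_a, "group_a", min_len=2)
    b = _as_array(group_b, "group_b", min_len=2)
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        raise ValidationError("both groups have zero variance: t statistic undefined")
    res = _sps.ttest_ind(a, b, equal_var=False)
    return TestResult(
        statistic=float(res.statistic),
        df=float(res.df),
        p_value=float(res.pvalue),
        method="Welch two-sample t-test",
    )


def _check_groups(groups: Sequence[Sequence[float]]) -> list[np.ndarray]:
    if len(groups) < 2:
        raise ValidationError("need at least two groups")
    arrs = [_as_array(g, f"group {i}", min_len=2) for i, g in enumerate(groups)]
    if all(a.var(ddof=1) == 0.0 for a in arrs):
        raise ValidationError("all groups have zero within-group variance: F undefined")
    return arrs


def one_way_anova(groups: Sequence[Sequence[float]]) -> TestResult:
    """One-way fixed-effects ANOVA: F with (k−1, N−k) degrees of freedom."""
    arrs = _check_groups(groups)
    res = _sps.f_oneway(*arrs)
    k = len(arrs)
    n_total = sum(a.size for a in arrs)
    return TestResult(
        statistic=float(res.statistic),
        df=(float(k - 1), float(n_total - k)),
        p_value=float(res.pvalue),
        method="one-way ANOVA",
    )


def tukey_hsd(groups: Sequence[Sequence[float]]) -> list[TestResult]:
    """All pairwise mean differences with studentized-range adjusted p-values.

    Statistic reported per pair (i, j) is mean_i − mean_j, as in the
    underlying honest-significant-difference procedure.
    """
    arrs = _check_groups(groups)
    res = _sps.tukey_hsd(*arrs)
    out: list[TestResult] = []
    k = len(arrs)
    n_total = sum(a.size for a in arrs)
    for i in range(k):
        for j in range(i + 1, k):
            out.append(
                TestResult(
                    statistic=float(res.statistic[i, j]),
                    df=(float(k), float(n_total - k)),
                    p_value=float(res.pvalue[i, j]),
                    method="Tukey HSD",
                    group_labels=(i, j),
                )
            )
    return out


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Pearson's r with a two-sided p-value from the t transform (df = n−2)."""
    xa = _as_array(x, "x", min_len=3)
    ya = _as_array(y, "y", min_len=3)
    if xa.size != ya.size:
        raise ValidationError(f"length mismatch: {xa.size} vs {ya.size}")
    if xa.var() == 0.0 or ya.var() == 0.0:
        raise ValidationError("zero variance: correlation undefined")
    res = _sps.pearsonr(xa, ya)
    return TestResult(
        statistic=float(res.statistic),
        df=float(xa.size - 2),
        p_value=float(res.pvalue),
        method="Pearson correlation",
    )
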