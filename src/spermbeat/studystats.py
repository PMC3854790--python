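"""Study-level summary statistics: mean ± s.d., 95% CI, Student's t test,
and count-derived percentages (mating outcomes, in-vitro fertilization
rates).

Conventions: values are reported as mean ± sample standard deviation
(n − 1 denominator); the 95% confidence half-width is 1.96 × s.e.m.; group
comparisons use the classic pooled-variance two-sample Student's t test
(Welch's correction available as an option); printed percentages are
rounded half-up at the displayed precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats as sps

from .errors import ParameterError

__all__ = ["GroupSummary", "CountPair", "TTestResult", "group_summary",
           "students_t", "percent", "pooled_rate"]


@dataclass
class GroupSummary:
    """n, mean, sample s.d., s.e.m. and 1.96 × s.e.m. half-width."""

    n: int
    mean: float
    sd: float
    sem: float
    ci95_halfwidth: float


@dataclass(frozen=True)
class CountPair:
    """successes out of total (e.g. pregnant females, 2-cell embryos)."""

    successes: int
    total: int

    def __post_init__(self) -> None:
        if self.total < 1:
            raise ParameterError("total must be >= 1")
        if not 0 <= self.successes <= self.total:
            raise ParameterError("successes must be in [0, total]")


@dataclass
class TTestResult:
    t: float
    df: float
    p: float


def group_summary(values) -> GroupSummary:
    """Summary of one group of measurements.

    For n = 1 the dispersion fields are NaN (the sample s.d. with n − 1
    denominator is undefined).
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ParameterError("empty group")
    n = int(x.size)
    mean = float(x.mean())
    if n < 2:
        return GroupSummary(n, mean, math.nan, math.nan, math.nan)
    sd = float(x.std(ddof=1))
    sem = sd / math.sqrt(n)
    return GroupSummary(n, mean, sd, sem, 1.96 * sem)


def students_t(group_a, group_b, welch: bool = False) -> TTestResult:
    """Two-sample t test; pooled-variance Student form by default.

    Degenerate case: if the pooled variance is zero the statistic is 0
    (p = 1) for equal means, and ±inf (p = 0) for unequal means.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ParameterError("each group needs n >= 2")
    if welch:
        res = sps.ttest_ind(a, b, equal_var=False)
        return TTestResult(float(res.statistic), float(res.df), float(res.pvalue))
    n1, n2 = a.size, b.size
    df = n1 + n2 - 2
    sp2 = (((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / df)
    diff = float(a.mean() - b.mean())
    if sp2 == 0:
        if diff == 0:
            return TTestResult(0.0, float(df), 1.0)
        return TTestResult(math.copysign(math.inf, diff), float(df), 0.0)
    t = diff / math.sqrt(sp2 * (1 / n1 + 1 / n2))
    p = 2 * float(sps.t.sf(abs(t), df))
    return TTestResult(float(t), float(df), p)


def percent(pair: CountPair, decimals: int = 0) -> float:
    """100 · successes / total, rounded half-up to ``decimals`` places."""
    q = Decimal(1).scaleb(-decimals)
    value = (Decimal(100) * Decimal(pair.successes) / Decimal(pair.total))
    return float(value.quantize(q, rounding=ROUND_HALF_UP))


def pooled_rate(pairs: list[CountPair], decimals: int = 0) -> float:
    """Percentage of summed successes over summed totals across experiments."""
    if not pairs:
        raise ParameterError("need at least one count pair")
    s = sum(p.successes for p in pairs)
    t = sum(p.total for p in pairs)
    if t == 0:
        raise ParameterError("all totals are zero")
    return percent(CountPair(s, t), decimals)
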