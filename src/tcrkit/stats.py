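"""Cohort comparison statistics: Welch t-tests, t-based 95% CIs, and OLS.

Conventions: all tests two-sided, significance threshold 0.05, no
multiplicity correction — a reporting convention, not enforced in code.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class GroupComparison:
    label_a: str
    label_b: str
    mean_a: float
    mean_b: float
    ci_a: tuple[float, float]
    ci_b: tuple[float, float]
    t_statistic: float
    welch_df: float
    p_two_sided: float


@dataclass(frozen=True)
class RegressionFit:
    slope: float
    intercept: float
    slope_ci: tuple[float, float]
    intercept_ci: tuple[float, float]
    r_squared: float
    n: int


def mean_ci(values, confidence: float = 0.95) -> tuple[float, float, float]:
    """(mean, lower, upper): mean +/- t_{1-(1-c)/2, n-1} * s / sqrt(n)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise StatsError("mean_ci needs at least 2 values")
    m = float(x.mean())
    se = float(x.std(ddof=1) / np.sqrt(x.size))
    tq = float(sps.t.ppf(0.5 + confidence / 2, df=x.size - 1))
    return m, m - tq * se, m + tq * se


def welch_t(a, b, label_a: str = "a", label_b: str = "b") -> GroupComparison:
    """Two-sided Welch t-test with Welch-Satterthwaite degrees of freedom."""
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size < 2 or y.size < 2:
        raise StatsError("each sample needs at least 2 values")
    va, vb = x.var(ddof=1), y.var(ddof=1)
    if va + vb == 0:
        raise StatsError("zero variance in both samples")
    res = sps.ttest_ind(x, y, equal_var=False)
    se2a, se2b = va / x.size, vb / y.size
    df = (se2a + se2b) ** 2 / (se2a**2 / (x.size - 1) + se2b**2 / (y.size - 1))
    return GroupComparison(
        label_a=label_a,
        label_b=label_b,
        mean_a=float(x.mean()),
        mean_b=float(y.mean()),
        ci_a=mean_ci(x)[1:] if x.std(ddof=1) > 0 else (float(x.mean()), float(x.mean())),
        ci_b=mean_ci(y)[1:] if y.std(ddof=1) > 0 else (float(y.mean()), float(y.mean())),
        t_statistic=float(res.statistic),
        welch_df=float(df),
        p_two_sided=float(res.pvalue),
    )


def ols_fit(x, y, confidence: float = 0.95) -> RegressionFit:
    """Simple least-squares line with t-based coefficient CIs.

    Closed-form slope/intercept; standard errors from the residual variance,
    matching the usual lm()-style output.
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    n = xv.size
    if n < 3:
        raise StatsError("ols_fit needs at least 3 points")
    if np.ptp(xv) == 0:
        raise StatsError("singular design: x is constant")
    xm, ym = xv.mean(), yv.mean()
    sxx = float(np.sum((xv - xm) ** 2))
    slope = float(np.sum((xv - xm) * (yv - ym)) / sxx)
    intercept = float(ym - slope * xm)
    resid = yv - (intercept + slope * xv)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((yv - ym) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    sigma2 = ss_res / (n - 2)
    se_slope = np.sqrt(sigma2 / sxx)
    se_inter = np.sqrt(sigma2 * (1.0 / n + xm**2 / sxx))
    tq = float(sps.t.ppf(0.5 + confidence / 2, df=n - 2))
    return RegressionFit(
        slope=slope,
        intercept=intercept,
        slope_ci=(slope - tq * se_slope, slope + tq * se_slope),
        intercept_ci=(intercept - tq * se_inter, intercept + tq * se_inter),
        r_squared=max(0.0, min(1.0, r2)),
        n=n,
    )
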