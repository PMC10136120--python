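"""Ratio-of-means heat-wave effect comparisons.

The overall heat-wave effect on a rate is summarised as the ratio
m = a/b of the mean daily rate under extreme conditions (a) to the mean
under mild conditions (b), computed either over females alive at day 10
("censored") or over all females ("uncensored").  Inference uses the
first-order delta method for independent groups:

    SE(m) = m * sqrt((SE_a/a)^2 + (SE_b/b)^2)

with a t-based 95% interval on a_n + b_n - 2 degrees of freedom.  Two
ratios are compared with t = (m1 - m2)/sqrt(SE1^2 + SE2^2); the default
degrees of freedom are the total of the four group sizes minus 4, with an
explicit override for reproducing published tables.  Relative changes are
reported as 100*(a - b)/b %.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["RatioResult", "RatioComparison", "ratio_of_means", "compare_ratios", "percent_change"]


@dataclass(frozen=True)
class RatioResult:
    ratio: float
    se: float
    ci_low: float | None = None
    ci_high: float | None = None
    a_mean: float | None = None
    a_se: float | None = None
    a_n: int | None = None
    b_mean: float | None = None
    b_se: float | None = None
    b_n: int | None = None
    censoring_mode: str = "uncensored"


@dataclass(frozen=True)
class RatioComparison:
    difference: float
    se: float
    t: float
    df: float
    p: float
    ratio_1: RatioResult = None
    ratio_2: RatioResult = None


def ratio_of_means(
    a_mean: float,
    a_se: float,
    a_n: int,
    b_mean: float,
    b_se: float,
    b_n: int,
    censoring_mode: str = "uncensored",
    conf: float = 0.95,
) -> RatioResult:
    """Delta-method ratio of two independent group means with 95% limits."""
    if b_mean == 0:
        raise ZeroDivisionError("denominator mean is zero; the ratio is undefined")
    if a_se < 0 or b_se < 0:
        raise ValueError("standard errors must be nonnegative")
    m = a_mean / b_mean
    se = abs(m) * np.sqrt((a_se / a_mean) ** 2 + (b_se / b_mean) ** 2)
    df = a_n + b_n - 2
    tcrit = stats.t.ppf(0.5 + conf / 2.0, df)
    return RatioResult(
        ratio=m,
        se=float(se),
        ci_low=float(m - tcrit * se),
        ci_high=float(m + tcrit * se),
        a_mean=a_mean,
        a_se=a_se,
        a_n=a_n,
        b_mean=b_mean,
        b_se=b_se,
        b_n=b_n,
        censoring_mode=censoring_mode,
    )


def compare_ratios(r1: RatioResult, r2: RatioResult, df: float | None = None) -> RatioComparison:
    """Two-sided t test for the difference between two independent ratios.

    Default df is the sum of the four underlying group sizes minus 4; pass
    ``df`` explicitly when the group sizes are unknown or when reproducing
    a published table with its printed df.
    """
    if r1.se <= 0 or r2.se <= 0:
        raise ValueError("both ratios must carry positive standard errors")
    diff = r1.ratio - r2.ratio
    se = float(np.sqrt(r1.se**2 + r2.se**2))
    t = diff / se
    if df is None:
        ns = (r1.a_n, r1.b_n, r2.a_n, r2.b_n)
        if any(n is None for n in ns):
            df = np.inf
        else:
            df = sum(ns) - 4
    p = float(2.0 * stats.t.sf(abs(t), df)) if np.isfinite(df) else float(
        2.0 * stats.norm.sf(abs(t))
    )
    return RatioComparison(difference=diff, se=se, t=float(t), df=df, p=p, ratio_1=r1, ratio_2=r2)


def percent_change(a_mean: float, b_mean: float) -> float:
    """Relative change 100*(a - b)/b in percent."""
    if b_mean == 0:
        raise ZeroDivisionError("reference mean is zero; percent change is undefined")
    return 100.0 * (a_mean - b_mean) / b_mean
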