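"""Pooled-SD standardized mean differences (Cohen's d), CIs and t-test power.

The effect size between two trajectory groups is

    d = (m1 - m2) / s_pooled,
    s_pooled^2 = [(n1-1) s1^2 + (n2-1) s2^2] / (n1 + n2 - 2),

with group 1 = transient-pain and group 2 = persistent-pain by convention,
so a more vulnerable persistent group yields a negative d.  The default
confidence interval is the large-sample normal approximation with
SE = sqrt((n1+n2)/(n1*n2) + d^2 / (2*(n1+n2))); an exact noncentral-t
interval and the Hedges small-sample correction are available as options.
Power for the two-sided two-sample t-test uses the noncentral-t distribution
with noncentrality d * sqrt(n1*n2/(n1+n2)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .cohort_io import LongCohort

__all__ = [
    "GroupSummary",
    "EffectSizeResult",
    "cohens_d",
    "cohens_d_from_samples",
    "d_confidence_interval",
    "smd_vs_baseline",
    "two_sample_power",
]


@dataclass(frozen=True)
class GroupSummary:
    """Sufficient statistics of the two groups (counts, means, sample SDs)."""

    n1: int
    n2: int
    m1: float
    m2: float
    s1: float
    s2: float

    def __post_init__(self) -> None:
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError("each group needs n >= 2")
        if self.s1 < 0 or self.s2 < 0:
            raise ValueError("SDs must be non-negative")


@dataclass
class EffectSizeResult:
    d: float
    pooled_sd: float
    ci_low: float | None = None
    ci_high: float | None = None
    level: float | None = None
    summary: GroupSummary | None = None

    def to_dict(self) -> dict:
        out = {"d": self.d, "pooled_sd": self.pooled_sd}
        if self.ci_low is not None:
            out.update(ci_low=self.ci_low, ci_high=self.ci_high, level=self.level)
        if self.summary is not None:
            s = self.summary
            out.update(n1=s.n1, n2=s.n2, m1=s.m1, m2=s.m2, s1=s.s1, s2=s.s2)
        return out


def cohens_d(summary: GroupSummary, hedges: bool = False) -> EffectSizeResult:
    """Pooled-SD Cohen's d from group summary statistics.

    ``hedges=True`` applies the small-sample bias correction
    J = 1 - 3/(4*df - 1); the uncorrected d is the default.
    """
    df = summary.n1 + summary.n2 - 2
    pooled_var = ((summary.n1 - 1) * summary.s1**2 + (summary.n2 - 1) * summary.s2**2) / df
    if pooled_var <= 0:
        raise ValueError("pooled variance is zero; d undefined")
    d = (summary.m1 - summary.m2) / np.sqrt(pooled_var)
    if hedges:
        d *= 1.0 - 3.0 / (4.0 * df - 1.0)
    return EffectSizeResult(d=float(d), pooled_sd=float(np.sqrt(pooled_var)), summary=summary)


def cohens_d_from_samples(
    x1: np.ndarray, x2: np.ndarray, level: float | None = 0.95,
    hedges: bool = False, ci_method: str = "normal",
) -> EffectSizeResult:
    """d between two samples (group 1 first), with an optional CI attached."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    x1, x2 = x1[~np.isnan(x1)], x2[~np.isnan(x2)]
    summary = GroupSummary(
        n1=len(x1), n2=len(x2),
        m1=float(np.mean(x1)), m2=float(np.mean(x2)),
        s1=float(np.std(x1, ddof=1)), s2=float(np.std(x2, ddof=1)),
    )
    res = cohens_d(summary, hedges=hedges)
    if level is not None:
        lo, hi = d_confidence_interval(res.d, summary.n1, summary.n2, level, method=ci_method)
        res.ci_low, res.ci_high, res.level = lo, hi, level
    return res


def _nct_ci(d: float, n1: int, n2: int, level: float) -> tuple[float, float]:
    """Exact CI by inverting the noncentral-t distribution of the t statistic."""
    scale = np.sqrt(n1 * n2 / (n1 + n2))
    df = n1 + n2 - 2
    t_obs = d * scale
    alpha = 1.0 - level
    span = abs(t_obs) + 20.0

    def upper(nc):  # P(T <= t_obs | nc) - alpha/2, decreasing in nc
        return stats.nct.cdf(t_obs, df, nc) - alpha / 2.0

    def lower(nc):
        return stats.nct.cdf(t_obs, df, nc) - (1.0 - alpha / 2.0)

    hi = optimize.brentq(upper, t_obs - 1e-9, t_obs + span)
    lo = optimize.brentq(lower, t_obs - span, t_obs + 1e-9)
    return lo / scale, hi / scale


def d_confidence_interval(
    d: float, n1: int, n2: int, level: float = 0.95, method: str = "normal"
) -> tuple[float, float]:
    """Confidence interval for a pooled-SD d.

    ``method='normal'`` (default): d +/- z * sqrt((n1+n2)/(n1*n2) + d^2/(2*(n1+n2))).
    ``method='noncentral_t'``: exact interval from the noncentral-t distribution.
    """
    if not (0 < level < 1):
        raise ValueError("confidence level must lie in (0, 1)")
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if method == "noncentral_t":
        return _nct_ci(d, n1, n2, level)
    if method != "normal":
        raise ValueError(f"unknown CI method {method!r}")
    z = stats.norm.ppf(0.5 + level / 2.0)
    se = np.sqrt((n1 + n2) / (n1 * n2) + d**2 / (2.0 * (n1 + n2)))
    return float(d - z * se), float(d + z * se)


def smd_vs_baseline(
    cohort: LongCohort, timepoint: str, baseline: str = "BASELINE",
    level: float = 0.95,
) -> EffectSizeResult:
    """Pooled-SD standardized mean difference of a visit versus baseline.

    Restricted to subjects observed at both visits; the follow-up sample is
    group 1, so rising pain gives a positive d.  (Whether a paired or pooled
    SD is the right denominator for within-subject contrasts is genuinely
    ambiguous; this implements the pooled two-sample form used for the
    between-trajectory comparisons.)
    """
    wide = cohort.to_wide()
    for lab in (timepoint, baseline):
        if lab not in wide.columns:
            raise KeyError(f"unknown timepoint {lab!r}")
    both = wide[[timepoint, baseline]].dropna()
    if len(both) < 2:
        raise ValueError("fewer than 2 subjects observed at both visits")
    return cohens_d_from_samples(both[timepoint].values, both[baseline].values, level=level)


def two_sample_power(d: float, n1: int, n2: int, alpha: float = 0.05) -> float:
    """Power of the two-sided two-sample t-test at effect size d.

    Uses the noncentral-t distribution with noncentrality
    d*sqrt(n1*n2/(n1+n2)); at d = 0 this returns alpha exactly.
    """
    if d < 0:
        raise ValueError("d must be non-negative (power is symmetric in sign)")
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    df = n1 + n2 - 2
    nc = d * np.sqrt(n1 * n2 / (n1 + n2))
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(stats.nct.sf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc))
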