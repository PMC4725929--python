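"""Welch two-sample t-tests from summary statistics or raw trait values."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["GroupSummary", "WelchResult", "welch_t_from_summary", "welch_t_from_values"]


@dataclass
class GroupSummary:
    """Label, sample mean, sample SD (n-1 divisor) and group size."""

    label: str
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if self.n < 2:
            raise ValueError("need n >= 2 per group")


@dataclass
class WelchResult:
    t: float
    df: float
    p_value: float


def welch_t_from_summary(g1: GroupSummary, g2: GroupSummary) -> WelchResult:
    """Welch's unequal-variance t-test from group summaries.

    t = (m1 - m2) / sqrt(s1^2/n1 + s2^2/n2), Welch–Satterthwaite degrees of
    freedom, two-sided p from the t distribution.
    """
    if g1.sd == 0 and g2.sd == 0:
        raise ValueError("both groups have zero variance: test is degenerate")
    v1 = g1.sd**2 / g1.n
    v2 = g2.sd**2 / g2.n
    t, p = stats.ttest_ind_from_stats(
        g1.mean, g1.sd, g1.n, g2.mean, g2.sd, g2.n, equal_var=False
    )
    df = (v1 + v2) ** 2 / (v1**2 / (g1.n - 1) + v2**2 / (g2.n - 1))
    return WelchResult(t=float(t), df=float(df), p_value=float(p))


def welch_t_from_values(values1, values2) -> WelchResult:
    """Welch's t-test on raw values; identical to the summary form applied to
    the groups' means and n-1 standard deviations."""
    a = np.asarray(values1, dtype=float)
    b = np.asarray(values2, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 values per group")
    return welch_t_from_summary(
        GroupSummary("group1", float(a.mean()), float(a.std(ddof=1)), a.size),
        GroupSummary("group2", float(b.mean()), float(b.std(ddof=1)), b.size),
    )
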