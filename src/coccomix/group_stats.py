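"""Descriptive hypothesis tests used to compare samples.

Thin wrappers over ``scipy.stats`` that return a uniform
:class:`TestResult` with the statistic, sample sizes, p-value and a flag
recording whether the p-value is exact or a (tie-corrected) normal /
chi-square approximation. All tests are two-sided; the Mann-Whitney
normal approximation uses a continuity correction. The t-test is
Welch's (unequal variances) with Welch-Satterthwaite degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "TestResult",
    "mann_whitney_u",
    "kruskal_wallis",
    "two_sample_t",
    "shapiro_wilk",
]

#: Largest tie-free total sample size for which the exact U null
#: distribution is enumerated rather than normally approximated.
_EXACT_U_LIMIT = 50


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    sample_sizes: tuple[int, ...]
    df: float | None = None
    exact_p: bool = False

    def __post_init__(self):
        if not 0 <= self.p_value <= 1:
            raise ValueError(f"p-value out of [0, 1]: {self.p_value}")


def _has_ties(*groups) -> bool:
    pooled = np.concatenate([np.asarray(g, float) for g in groups])
    return np.unique(pooled).size < pooled.size


def mann_whitney_u(a: Sequence[float], b: Sequence[float],
                   continuity: bool = True) -> TestResult:
    """Two-sided Mann-Whitney U test.

    The U statistic counts pairs ``a_i < b_j`` plus half-ties. The exact
    null distribution is used for small tie-free inputs; otherwise the
    tie-corrected normal approximation (with continuity correction by
    default) is used and ``exact_p`` is False.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    exact = not _has_ties(a, b) and (a.size + b.size) <= _EXACT_U_LIMIT
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=continuity,
    )
    return TestResult(
        statistic=float(res.statistic), p_value=float(res.pvalue),
        method="mann-whitney-u", sample_sizes=(a.size, b.size),
        exact_p=exact,
    )


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Kruskal-Wallis rank test: tie-corrected H with chi-square p-value."""
    arrays = [np.asarray(g, float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size == 0 for g in arrays):
        raise ValueError("all groups must be nonempty")
    if all(np.array_equal(arrays[0], g) for g in arrays[1:]):
        # degenerate identical-group case: H = 0 by construction
        return TestResult(
            statistic=0.0, p_value=1.0, method="kruskal-wallis",
            sample_sizes=tuple(g.size for g in arrays),
            df=float(len(arrays) - 1), exact_p=False,
        )
    res = stats.kruskal(*arrays)
    return TestResult(
        statistic=float(res.statistic), p_value=float(res.pvalue),
        method="kruskal-wallis",
        sample_sizes=tuple(g.size for g in arrays),
        df=float(len(arrays) - 1), exact_p=False,
    )


def two_sample_t(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Welch two-sample t-test (two-sided, unequal variances)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples need at least 2 values")
    res = stats.ttest_ind(a, b, equal_var=False)
    return TestResult(
        statistic=float(res.statistic), p_value=float(res.pvalue),
        method="welch-t", sample_sizes=(a.size, b.size),
        df=float(res.df), exact_p=False,
    )


def shapiro_wilk(values: Sequence[float]) -> TestResult:
    """Shapiro-Wilk normality test (3 <= n <= 5000)."""
    arr = np.asarray(values, float)
    if not 3 <= arr.size <= 5000:
        raise ValueError(f"Shapiro-Wilk requires 3 <= n <= 5000, got {arr.size}")
    res = stats.shapiro(arr)
    return TestResult(
        statistic=float(res.statistic), p_value=float(res.pvalue),
        method="shapiro-wilk", sample_sizes=(arr.size,), exact_p=False,
    )
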