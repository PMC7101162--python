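"""Filtering and descriptive statistics applied before mixture modelling.

The pipeline applies, per sample and in this order: (1) single-pass Tukey
outlier removal on the pooled thickness values, (2) exclusion of
morphotypes rarer than 1% relative abundance, (3) relative abundances
with binomial count margins of error for reporting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("coccomix")


@dataclass(frozen=True)
class SummaryStat:
    """Sample mean with a t-based 95% confidence half-width."""

    n: int
    mean: float
    ci_half_width: float

    def __post_init__(self):
        if self.ci_half_width < 0:
            raise ValueError("ci_half_width must be >= 0")


def remove_outliers(
    values: Sequence[float], multiplier: float = 1.5
) -> tuple[list[float], list[float]]:
    """Partition ``values`` into (kept, removed) by the Tukey fence.

    A value is removed when it lies outside
    ``[Q1 - multiplier*IQR, Q3 + multiplier*IQR]`` with quartiles taken by
    linear interpolation between order statistics. This is a single pass:
    the fences are computed once from the full input and never
    re-iterated on the kept subset. Order is preserved in both outputs.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError("values must be one-dimensional")
    if arr.size < 4:
        raise ValueError(
            f"need at least 4 values to define quartile fences, got {arr.size}"
        )
    if not np.isfinite(arr).all():
        raise ValueError("values must all be finite")
    q1, q3 = np.quantile(arr, [0.25, 0.75])  # linear ("type 7") interpolation
    iqr = q3 - q1
    lo, hi = q1 - multiplier * iqr, q3 + multiplier * iqr
    inside = (arr >= lo) & (arr <= hi)
    kept = arr[inside].tolist()
    removed = arr[~inside].tolist()
    if removed:
        logger.info(
            "outlier fence [%.4g, %.4g]: removed %d of %d values",
            lo, hi, len(removed), arr.size,
        )
    return kept, removed


def relative_abundance(
    counts: Mapping[str, int], confidence: float = 0.95
) -> pd.DataFrame:
    """Relative abundance per morphotype with a binomial count margin.

    Returns a DataFrame indexed by morphotype with columns ``count``,
    ``relative_abundance`` and ``margin_of_error``; the margin is the
    normal-approximation (Wald) half-width ``z * sqrt(p(1-p)/n)`` at the
    requested confidence level.
    """
    if not 0 < confidence < 1:
        raise ValueError("confidence must be in (0, 1)")
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("total count must be > 0")
    if any(c < 0 for c in counts.values()):
        raise ValueError("counts must be >= 0")
    z = stats.norm.ppf(0.5 + confidence / 2)
    rows = {}
    for morph, c in counts.items():
        p = c / total
        rows[morph] = {
            "count": c,
            "relative_abundance": p,
            "margin_of_error": z * np.sqrt(p * (1 - p) / total),
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "morphotype"
    table["count"] = table["count"].astype(int)
    return table


def filter_rare(
    counts: Mapping[str, int], threshold: float = 0.01
) -> set[str]:
    """Morphotypes whose relative abundance is at least ``threshold``.

    Morphotypes strictly below the threshold (1% by default) are dropped
    from the mixture model; the retained set is returned.
    """
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("total count must be > 0")
    retained = {m for m, c in counts.items() if c / total >= threshold}
    dropped = set(counts) - retained
    if dropped:
        logger.info(
            "dropped rare morphotype(s) %s (< %.1f%% relative abundance)",
            sorted(dropped), 100 * threshold,
        )
    return retained


def summarize(values: Sequence[float], confidence: float = 0.95) -> SummaryStat:
    """Mean and t-based confidence half-width of a measurement column."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 values for a confidence interval")
    sem = arr.std(ddof=1) / np.sqrt(arr.size)
    tcrit = stats.t.ppf(0.5 + confidence / 2, df=arr.size - 1)
    return SummaryStat(n=int(arr.size), mean=float(arr.mean()),
                       ci_half_width=float(tcrit * sem))


def preprocessing_report(
    thickness: Sequence[float],
    counts: Mapping[str, int],
    *,
    outlier_multiplier: float = 1.5,
    rare_threshold: float = 0.01,
) -> tuple[list[float], dict[str, int], pd.DataFrame]:
    """Run the per-sample preprocessing and report what was removed.

    Returns the kept thickness values, the retained morphotype counts
    (input order preserved) and a one-row report DataFrame.
    """
    kept, removed = remove_outliers(thickness, outlier_multiplier)
    retained = filter_rare(counts, rare_threshold)
    kept_counts = {m: c for m, c in counts.items() if m in retained}
    report = pd.DataFrame(
        [{
            "n_thickness": len(thickness),
            "n_outliers_removed": len(removed),
            "outliers": ";".join(f"{v:.4g}" for v in removed),
            "morphotypes_excluded": ";".join(
                sorted(set(counts) - retained)),
        }]
    )
    return kept, kept_counts, report
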