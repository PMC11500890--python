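"""Imaging-time-interval analysis of similarity scores.

The elapsed days between the past and recent radiograph of each pair are
cut into 100-day units.  For every 100-day threshold a separate one-dummy
regression Y = b0 + b1*X is fitted, where X indicates an interval at or
above the threshold and Y is the pair's similarity score; with a single
binary regressor the OLS solution is the pair of group means, so the fits
are closed-form.  The coefficient sequence b1(threshold) is then scanned
for the 100-day section where it changes fastest; the midpoint of that
section is the cut-off separating "short" from "long" intervals, and the
two groups are compared with a pooled two-sample t-test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Literal, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "IntervalDataset",
    "IntervalRegressionSweep",
    "GroupComparison",
    "make_dummy",
    "count_thresholds",
    "fit_binary_ols",
    "sweep_regressions",
    "select_cutoff",
    "compare_groups",
    "days_to_years",
]

logger = logging.getLogger(__name__)

DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class IntervalDataset:
    """Per-pair (interval in days, similarity score) observations."""

    interval_days: np.ndarray
    similarity: np.ndarray

    def __post_init__(self) -> None:
        days = np.asarray(self.interval_days, dtype=np.int64)
        sim = np.asarray(self.similarity, dtype=float)
        if days.shape != sim.shape or days.ndim != 1:
            raise ValueError("interval_days and similarity must be aligned 1-D")
        if days.size == 0:
            raise ValueError("dataset is empty")
        if (days < 1).any():
            raise ValueError("interval_days must be >= 1")
        object.__setattr__(self, "interval_days", days)
        object.__setattr__(self, "similarity", sim)

    def __len__(self) -> int:
        return int(self.interval_days.size)


@dataclass(frozen=True)
class IntervalRegressionSweep:
    """The per-threshold regression fits and the selected cut-off.

    ``coefficients`` holds b1 per threshold (NaN where a dummy group was
    empty and the fit is undefined); ``selected_section`` is the 100-day
    span whose endpoints are the two thresholds between which b1 jumped
    the most, and ``cutoff_days`` its midpoint.
    """

    thresholds: np.ndarray
    intercepts: np.ndarray
    coefficients: np.ndarray
    n0: np.ndarray
    n1: np.ndarray
    selected_section: tuple[float, float]
    cutoff_days: float


@dataclass(frozen=True)
class GroupComparison:
    """Short- vs long-interval similarity comparison (two-sample t-test)."""

    cutoff_days: float
    n_short: int
    n_long: int
    mean_short: float
    sd_short: float
    mean_long: float
    sd_long: float
    t_statistic: float
    p_value: float
    variant: str


def make_dummy(interval_days: int, threshold_days: int) -> int:
    """1 if the interval is at or above the threshold, else 0.

    Equality goes to the dummy=1 (long-interval) group, matching the
    ">= cutoff" convention of the final group split.
    """
    if interval_days <= 0 or threshold_days <= 0:
        raise ValueError("interval_days and threshold_days must be positive")
    return int(interval_days >= threshold_days)


def count_thresholds(min_days: int, max_days: int, unit: int = 100) -> int:
    """Number of unit-multiples usable as thresholds on [min_days, max_days].

    A multiple t of ``unit`` is usable when min_days < t <= max_days: at
    t <= min_days every observation is in the dummy=1 group and at
    t > max_days every observation is in the dummy=0 group, so neither
    splits the data.
    """
    if min_days > max_days:
        raise ValueError("min_days must not exceed max_days")
    if unit <= 0:
        raise ValueError("unit must be positive")
    return max_days // unit - min_days // unit


def fit_binary_ols(
    dataset: IntervalDataset, threshold_days: int
) -> tuple[float, float]:
    """Closed-form OLS of similarity on the single threshold dummy.

    b0 is the mean similarity of the dummy=0 (short) group and b1 the
    long-group mean minus the short-group mean.  Raises if either group is
    empty (the fit is undefined at such a threshold).
    """
    dummy = dataset.interval_days >= threshold_days
    if dummy.all() or not dummy.any():
        raise ValueError(
            f"degenerate threshold {threshold_days}: one dummy group is empty"
        )
    mean0 = float(dataset.similarity[~dummy].mean())
    mean1 = float(dataset.similarity[dummy].mean())
    return mean0, mean1 - mean0


def sweep_regressions(
    dataset: IntervalDataset,
    unit_days: int = 100,
    trend: Literal["first_difference", "second_difference"] = "first_difference",
) -> IntervalRegressionSweep:
    """Fit the dummy regression at every unit-multiple threshold.

    Thresholds are the multiples of ``unit_days`` in (min interval, max
    interval]; degenerate thresholds are recorded as NaN and excluded from
    the trend scan.  The cut-off is chosen by :func:`select_cutoff`.
    """
    lo = int(dataset.interval_days.min())
    hi = int(dataset.interval_days.max())
    n_thresholds = count_thresholds(lo, hi, unit_days)
    first = (lo // unit_days + 1) * unit_days
    thresholds = first + unit_days * np.arange(n_thresholds, dtype=np.int64)
    if n_thresholds < 2:
        raise ValueError(
            f"only {n_thresholds} usable thresholds on [{lo}, {hi}] days; "
            "need at least 2 for a trend"
        )
    b0 = np.full(n_thresholds, np.nan)
    b1 = np.full(n_thresholds, np.nan)
    n0 = np.zeros(n_thresholds, dtype=np.int64)
    n1 = np.zeros(n_thresholds, dtype=np.int64)
    for k, t in enumerate(thresholds):
        dummy = dataset.interval_days >= t
        n1[k] = int(dummy.sum())
        n0[k] = len(dataset) - n1[k]
        if n0[k] == 0 or n1[k] == 0:
            logger.warning("threshold %d days is degenerate; coefficient NaN", t)
            continue
        b0[k], b1[k] = fit_binary_ols(dataset, int(t))
    section, cutoff = select_cutoff(thresholds, b1, trend=trend)
    return IntervalRegressionSweep(
        thresholds=thresholds,
        intercepts=b0,
        coefficients=b1,
        n0=n0,
        n1=n1,
        selected_section=section,
        cutoff_days=cutoff,
    )


def select_cutoff(
    thresholds: Sequence[float],
    coefficients: Sequence[float],
    trend: Literal["first_difference", "second_difference"] = "first_difference",
) -> tuple[tuple[float, float], float]:
    """Locate the section where the coefficient trend changes fastest.

    Scans consecutive *defined* coefficients and picks the section between
    the two thresholds with the largest absolute change of b1 (or of its
    first difference when ``trend="second_difference"``).  Ties go to the
    earliest section.  Returns ``((lower, upper), midpoint)``.
    """
    t = np.asarray(thresholds, dtype=float)
    b = np.asarray(coefficients, dtype=float)
    defined = ~np.isnan(b)
    t, b = t[defined], b[defined]
    if b.size < 2:
        raise ValueError("need at least 2 defined coefficients")
    if trend == "first_difference":
        deltas = np.abs(np.diff(b))
        offset = 0
    elif trend == "second_difference":
        if b.size < 3:
            raise ValueError("need at least 3 defined coefficients")
        deltas = np.abs(np.diff(b, n=2))
        offset = 1
    else:
        raise ValueError(f"unknown trend criterion: {trend!r}")
    k = int(np.argmax(deltas)) + offset  # argmax takes the earliest maximum
    if (deltas == deltas[int(np.argmax(deltas))]).sum() > 1:
        logger.info("trend-change tie; earliest section selected")
    section = (float(t[k]), float(t[k + 1]))
    return section, (section[0] + section[1]) / 2.0


def compare_groups(
    dataset: IntervalDataset,
    cutoff_days: float,
    variant: Literal["student", "welch"] = "student",
) -> GroupComparison:
    """Two-sample t-test of similarity between short and long intervals.

    Pairs with interval >= ``cutoff_days`` form the long group.  The
    default is the pooled-variance Student test; Welch is available behind
    the ``variant`` flag.  With zero variance in both groups the statistic
    is undefined and reported as NaN.
    """
    long_mask = dataset.interval_days >= cutoff_days
    short = dataset.similarity[~long_mask]
    long = dataset.similarity[long_mask]
    if short.size == 0 or long.size == 0:
        raise ValueError(f"cutoff {cutoff_days} days leaves an empty group")
    with np.errstate(invalid="ignore"):  # zero-variance groups give NaN t
        t_stat, p = stats.ttest_ind(short, long, equal_var=(variant == "student"))
    return GroupComparison(
        cutoff_days=float(cutoff_days),
        n_short=int(short.size),
        n_long=int(long.size),
        mean_short=float(short.mean()),
        sd_short=float(short.std(ddof=1)) if short.size > 1 else float("nan"),
        mean_long=float(long.mean()),
        sd_long=float(long.std(ddof=1)) if long.size > 1 else float("nan"),
        t_statistic=float(t_stat),
        p_value=float(p),
        variant=variant,
    )


def days_to_years(days: float) -> float:
    """Convert days to years (365.25 d/y), rounded half-up to one decimal."""
    if days <= 0:
        raise ValueError("days must be positive")
    years = Decimal(days) / Decimal(DAYS_PER_YEAR)
    return float(years.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
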