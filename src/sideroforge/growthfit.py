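"""Maximal specific growth rate estimation from OD time series.

The estimator is the rolling log-linear ("easy linear") method: ordinary
least squares of ln(OD) against time over every contiguous window of fixed
length, reporting the steepest slope among windows whose r-squared reaches a
quota (default 0.95) of the best window's r-squared — the quota keeps noisy
low-OD windows from inflating the maximum. Ties are broken by higher
r-squared, then by the earliest window. Rates are per hour.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "GrowthCurve",
    "GrowthRateEstimate",
    "InsufficientDataError",
    "fit_growth_rate",
    "compare_rates",
]

DEFAULT_WINDOW = 5
DEFAULT_QUOTA = 0.95


class InsufficientDataError(ValueError):
    """Too few usable points for the requested fit."""


@dataclass(frozen=True)
class GrowthCurve:
    """One replicate OD610 time course."""

    condition: str
    replicate: str
    times: tuple[float, ...]
    od: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.times) != len(self.od):
            raise ValueError("times and OD values must have equal length")
        t = np.asarray(self.times, dtype=float)
        if len(t) >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError("time points must be strictly increasing")


@dataclass(frozen=True)
class GrowthRateEstimate:
    """Maximal specific growth rate with its fit window and quality."""

    mu: float
    window_start: int
    window_end: int
    r_squared: float
    n_points: int


def _window_fit(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """OLS slope and r-squared of y ~ t; constant y is a perfect zero slope."""
    t_c = t - t.mean()
    y_c = y - y.mean()
    sxx = float(t_c @ t_c)
    syy = float(y_c @ y_c)
    sxy = float(t_c @ y_c)
    slope = sxy / sxx
    if syy == 0.0:
        return slope, 1.0
    r2 = (sxy * sxy) / (sxx * syy)
    return slope, r2


def fit_growth_rate(
    curve: GrowthCurve, window: int = DEFAULT_WINDOW, quota: float = DEFAULT_QUOTA
) -> GrowthRateEstimate:
    """Maximal slope of ln(OD) versus time over contiguous windows.

    Only windows with ``r_squared >= quota * max(r_squared)`` compete for the
    maximum; set ``quota=0`` for the unfiltered maximal slope.
    """
    if window < 2:
        raise ValueError("window must span at least 2 points")
    if not 0.0 <= quota <= 1.0:
        raise ValueError("quota must be in [0, 1]")
    t = np.asarray(curve.times, dtype=float)
    od = np.asarray(curve.od, dtype=float)
    keep = od > 0
    if not np.all(keep):
        logger.warning(
            "curve %s/%s: excluding %d non-positive OD value(s)",
            curve.condition,
            curve.replicate,
            int((~keep).sum()),
        )
        t, od = t[keep], od[keep]
    if len(od) < window:
        raise InsufficientDataError(
            f"need at least {window} positive points, have {len(od)}"
        )
    log_od = np.log(od)
    fits = [
        _window_fit(t[start : start + window], log_od[start : start + window])
        for start in range(len(od) - window + 1)
    ]
    r2_cut = quota * max(r2 for _, r2 in fits)
    best: tuple[float, float, int] | None = None  # (mu, r2, start)
    for start, (slope, r2) in enumerate(fits):
        if r2 < r2_cut:
            continue
        if best is None or (slope, r2, -start) > (best[0], best[1], -best[2]):
            best = (slope, r2, start)
    mu, r2, start = best
    return GrowthRateEstimate(
        mu=mu,
        window_start=start,
        window_end=start + window - 1,
        r_squared=min(max(r2, 0.0), 1.0),
        n_points=window,
    )


def compare_rates(
    a: Sequence[GrowthRateEstimate | float],
    b: Sequence[GrowthRateEstimate | float],
) -> tuple[float, float]:
    """Two-sided Welch comparison of replicate growth rates.

    Returns (mean difference a - b, p value). Requires at least two
    replicates per group. Two identical zero-variance groups give p = 1.
    """
    mu_a = np.asarray([x.mu if isinstance(x, GrowthRateEstimate) else float(x) for x in a])
    mu_b = np.asarray([x.mu if isinstance(x, GrowthRateEstimate) else float(x) for x in b])
    if len(mu_a) < 2 or len(mu_b) < 2:
        raise InsufficientDataError("at least two replicates per group are required")
    diff = float(mu_a.mean() - mu_b.mean())
    if mu_a.var(ddof=1) == 0.0 and mu_b.var(ddof=1) == 0.0:
        return diff, 1.0 if diff == 0.0 else 0.0
    t_stat, p_value = stats.ttest_ind(mu_a, mu_b, equal_var=False)
    return diff, float(p_value)
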