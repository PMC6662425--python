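"""Occurrence-record range expansion and the lag-phase test.

Dated occurrence records are binned into ~1 km^2 spatial units by rounding
latitude and longitude to the nearest hundredth of a degree (ties rounded
half away from zero, via decimal arithmetic so the behaviour is platform
independent). The accumulation curve counts spatial units first occupied up
to each year; a lag phase is probed by ordinary least squares of log10
cumulative occupied units on year — an exponential (lag-free) expansion is
log-linear, so a poor linear fit and a preferred single-breakpoint (hinge)
model are the lag diagnostics. The verdict is left to the caller; the fit
statistics (slope b, R^2, F, df, p) and a dAIC for the hinge comparison are
reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


def _round_half_away(x: float, digits: int = 2) -> float:
    """Round half away from zero using decimal arithmetic."""
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def bin_records(records: pd.DataFrame) -> dict[tuple[float, float], int]:
    """Occupancy grid: (lat, lon) rounded to hundredths -> first year observed."""
    grid: dict[tuple[float, float], int] = {}
    for year, lat, lon in zip(records["year"], records["lat"], records["lon"]):
        cell = (_round_half_away(lat), _round_half_away(lon))
        y = int(year)
        if cell not in grid or y < grid[cell]:
            grid[cell] = y
    return grid


def accumulation_curve(
    grid: dict[tuple[float, float], int],
    year_range: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Per-year newly occupied and cumulative occupied cell counts.

    Years with zero new cells are included. ``year_range`` defaults to the
    span of first-occupancy years in the grid.
    """
    if not grid:
        raise ValueError("empty occupancy grid")
    first_years = np.array(sorted(grid.values()))
    if year_range is None:
        year_range = (int(first_years.min()), int(first_years.max()))
    years = np.arange(year_range[0], year_range[1] + 1)
    new = np.array([(first_years == y).sum() for y in years])
    cumulative = np.array([(first_years <= y).sum() for y in years])
    return pd.DataFrame({"year": years, "new_cells": new,
                         "cumulative_cells": cumulative})


@dataclass
class LagPhaseFit:
    """OLS of log10 cumulative occupied cells on year."""

    slope: float
    intercept: float
    r_squared: float
    f_statistic: float
    df: tuple[int, int]
    p_value: float
    n_years: int
    flagged: bool = False  # degenerate fit (constant cumulative)


def lag_phase_regression(curve: pd.DataFrame) -> LagPhaseFit:
    """Fit log10(cumulative) ~ year over years with cumulative > 0.

    A high R^2 is the lag-free signature (exponential spread is exactly
    log-linear); the caller decides the threshold. Constant cumulative counts
    give a zero slope with a flagged, undefined R^2 reported as 0.
    """
    use = curve[curve["cumulative_cells"] > 0]
    if len(use) < 3:
        raise ValueError("lag regression needs >= 3 years with occupancy")
    x = use["year"].to_numpy(float)
    y = np.log10(use["cumulative_cells"].to_numpy(float))
    n = len(x)
    if np.allclose(y, y[0]):
        logger.warning("cumulative range constant; regression degenerate")
        return LagPhaseFit(0.0, float(y[0]), 0.0, 0.0, (1, n - 2), np.nan,
                           n, flagged=True)
    res = stats.linregress(x, y)
    r2 = res.rvalue ** 2
    f = (n - 2) * r2 / (1 - r2) if r2 < 1 else np.inf
    return LagPhaseFit(
        slope=float(res.slope), intercept=float(res.intercept),
        r_squared=float(r2), f_statistic=float(f), df=(1, n - 2),
        p_value=float(res.pvalue), n_years=n,
    )


def _aic(rss: float, n: int, k: int) -> float:
    rss = max(rss, 1e-300)
    return n * np.log(rss / n) + 2 * k


def breakpoint_comparison(curve: pd.DataFrame) -> dict:
    """Compare the straight-line fit against a hinge (flat-then-linear) fit.

    The hinge model ``log10(cum) = a + b * max(0, year - tau)`` captures a
    lag phase of length ``tau - first_year``. Returns both AICs and
    ``delta_aic = AIC(line) - AIC(hinge)``; values > 2 favour a lag.
    """
    use = curve[curve["cumulative_cells"] > 0]
    if len(use) < 5:
        raise ValueError("breakpoint comparison needs >= 5 years with occupancy")
    x = use["year"].to_numpy(float)
    y = np.log10(use["cumulative_cells"].to_numpy(float))
    n = len(x)
    res = stats.linregress(x, y)
    rss_line = float(np.sum((y - (res.intercept + res.slope * x)) ** 2))
    aic_line = _aic(rss_line, n, 3)  # intercept, slope, sigma

    best_rss, best_tau = np.inf, None
    for tau in x[1:-2]:  # need >=2 points on each side
        z = np.maximum(0.0, x - tau)
        A = np.column_stack([np.ones(n), z])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        rss = float(np.sum((y - A @ coef) ** 2))
        if rss < best_rss:
            best_rss, best_tau = rss, float(tau)
    aic_hinge = _aic(best_rss, n, 4)  # intercept, slope, breakpoint, sigma
    return {
        "aic_line": aic_line,
        "aic_hinge": aic_hinge,
        "delta_aic": aic_line - aic_hinge,
        "breakpoint_year": best_tau,
        "lag_preferred": (aic_line - aic_hinge) > 2,
    }
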