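"""Temporal aggregation and least-squares trend analysis.

Trends are fitted on annual means (never on raw monthly values, which carry
seasonal autocorrelation); significance comes from the Pearson correlation
via the exact t transform.  The 12-term smoother is a display filter only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class MonthlySeries:
    """A named monthly band series with gaps allowed."""

    variable: str
    units: str
    band_id: int | None
    data: pd.Series  # monthly PeriodIndex -> value

    def __post_init__(self) -> None:
        idx = pd.PeriodIndex(self.data.index, freq="M")
        if idx.has_duplicates:
            raise ValueError("at most one value per (year, month)")
        if not idx.is_monotonic_increasing:
            order = np.argsort(idx)
            self.data = self.data.iloc[order]
            idx = idx[order]
        self.data = pd.Series(np.asarray(self.data, dtype=float), index=idx)

    @classmethod
    def from_items(cls, variable, units, band_id, items) -> "MonthlySeries":
        """Build from an iterable of ((year, month), value)."""
        keys, vals = zip(*items)
        idx = pd.PeriodIndex([pd.Period(year=y, month=m, freq="M") for y, m in keys])
        return cls(variable, units, band_id, pd.Series(vals, index=idx))


@dataclass(frozen=True)
class TrendResult:
    slope_per_decade: float
    intercept: float
    pearson_r: float
    p_value: float
    n_points: int


#: Centered 13-point filter with half weights on the extreme months, so the
#: window spans exactly 12 months of phase and annihilates the annual cycle.
_MA12_WEIGHTS = np.concatenate(([0.5], np.ones(11), [0.5])) / 12.0


def moving_average_12(series: MonthlySeries) -> MonthlySeries:
    """Centered 12-term moving average; undefined at edges and across gaps."""
    data = series.data
    full = data.reindex(pd.period_range(data.index[0], data.index[-1], freq="M"))
    vals = np.asarray(full, dtype=float)
    n = len(vals)
    out = np.full(n, np.nan)
    if n >= 13:
        win = np.lib.stride_tricks.sliding_window_view(vals, 13)
        smoothed = win @ _MA12_WEIGHTS  # NaN wherever any window value is NaN
        out[6 : n - 6] = smoothed
    return MonthlySeries(series.variable, series.units, series.band_id,
                         pd.Series(out, index=full.index))


def annual_mean(series: MonthlySeries, min_months: int = 9) -> pd.Series:
    """Calendar-year means; years with fewer than min_months values are NaN."""
    data = series.data.dropna()
    years = data.index.year
    grouped = data.groupby(years)
    means = grouped.mean()
    counts = grouped.count()
    means[counts < min_months] = np.nan
    means.index.name = "year"
    return means


def linear_trend(years, values) -> TrendResult:
    """OLS of value on year with Pearson significance.

    slope_per_decade = 10 x per-year slope; two-sided p from
    t = r sqrt((n-2)/(1-r^2)) on n-2 df.  A zero-variance response is the
    degenerate no-trend case: slope 0, r 0, p 1.
    """
    x = np.asarray(years, dtype=float)
    y = np.asarray(values, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = len(np.unique(x))
    if n < 3:
        raise ValueError(f"linear_trend needs >=3 distinct years, got {n}")
    if np.ptp(y) == 0.0:
        return TrendResult(0.0, float(y[0]), 0.0, 1.0, len(x))
    fit = stats.linregress(x, y)
    return TrendResult(
        slope_per_decade=10.0 * fit.slope,
        intercept=fit.intercept,
        pearson_r=fit.rvalue,
        p_value=fit.pvalue,
        n_points=len(x),
    )


def trend_series(series: MonthlySeries, min_months: int = 9) -> TrendResult:
    """Annual-mean then linear_trend convenience wrapper."""
    yearly = annual_mean(series, min_months=min_months).dropna()
    return linear_trend(yearly.index.to_numpy(), yearly.to_numpy())


def _annual_mean_cube(values, years_axis, min_months=9):
    """Cell-wise annual means of a (time, ...) cube -> (n_years, ...)."""
    uyears = np.unique(years_axis)
    out = np.full((len(uyears),) + values.shape[1:], np.nan)
    for k, yr in enumerate(uyears):
        sl = values[years_axis == yr]
        finite = np.isfinite(sl)
        cnt = finite.sum(axis=0)
        tot = np.where(finite, sl, 0.0).sum(axis=0)
        with np.errstate(invalid="ignore"):
            mean = tot / np.maximum(cnt, 1)
        out[k] = np.where(cnt >= min_months, mean, np.nan)
    return uyears, out


def trend_map(field, years=None, min_months: int = 9, alpha: float = 0.05):
    """Cell-wise trend of annual means.

    Parameters
    ----------
    field : geo.GridField
    years : optional (y0, y1) inclusive range restriction.

    Returns (slope_per_decade 2D, p_value 2D, significant 2D bool); cells with
    fewer than 3 annual values are NaN / False.
    """
    vals = field.values
    yaxis = field.years
    if years is not None:
        keep = (yaxis >= years[0]) & (yaxis <= years[1])
        vals, yaxis = vals[keep], yaxis[keep]
    uyears, annual = _annual_mean_cube(vals, yaxis, min_months=min_months)
    x = uyears.astype(float)[:, None, None]
    finite = np.isfinite(annual)
    n = finite.sum(axis=0).astype(float)
    ok = n >= 3
    xm = np.where(finite, x, 0.0)
    ym = np.where(finite, annual, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        xbar = xm.sum(0) / n
        ybar = ym.sum(0) / n
        sxx = (np.where(finite, (x - xbar) ** 2, 0.0)).sum(0)
        syy = (np.where(finite, (annual - ybar) ** 2, 0.0)).sum(0)
        sxy = (np.where(finite, (x - xbar) * (annual - ybar), 0.0)).sum(0)
        slope = sxy / sxx
        r = sxy / np.sqrt(sxx * syy)
        r = np.clip(r, -1.0, 1.0)
        t = r * np.sqrt((n - 2) / np.maximum(1e-300, 1.0 - r**2))
        p = 2.0 * stats.t.sf(np.abs(t), np.maximum(n - 2, 1))
    zero_var = ok & (syy == 0.0)
    slope = np.where(ok, slope, np.nan)
    p = np.where(ok, p, np.nan)
    slope[zero_var] = 0.0
    p[zero_var] = 1.0
    sig = ok & (p < alpha)
    return 10.0 * slope, p, sig


def star_code(p: float) -> str:
    """Significance stars: thresholds 0.05 / 0.01 / 0.001 / 0.0001."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 1e-2:
        return "**"
    if p < 0.05:
        return "*"
    return ""
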