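"""Two-period SST climatologies, isotherm tracing and displacement.

Isotherms are traced per longitude column by scanning cell centers south to
north and linearly interpolating the first (southernmost) sign change of
clim - T; columns with several crossings are flagged rather than guessed at.
Displacements are along-meridian great-circle distances, positive northward.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import geo
from .geo import KM_PER_DEG_LAT

DEFAULT_ISOTHERMS = (18.5, 20.0, 22.0, 24.0)


@dataclass
class PeriodClimatology:
    """Cell-wise mean SST over a year range (all months by default)."""

    values: np.ndarray  # (n_lat, n_lon), NaN where under-sampled
    grid: geo.GridSpec
    year_range: tuple[int, int]
    n_years: np.ndarray | None = None  # contributing years per cell


@dataclass
class IsothermTrace:
    temperature: float
    lons: np.ndarray  # longitude column centers with a crossing
    lats: np.ndarray  # interpolated crossing latitude per column
    multiple: np.ndarray  # True where the column had >1 crossing


@dataclass(frozen=True)
class IsothermShiftResult:
    temperature: float
    coastal_km: float
    offshore_km: float
    n_coastal: int
    n_offshore: int


def period_mean(
    fld: geo.GridField,
    years: tuple[int, int],
    min_years: int = 10,
) -> PeriodClimatology:
    """Cell-wise mean over all months of the inclusive year range."""
    y0, y1 = years
    keep = (fld.years >= y0) & (fld.years <= y1)
    if not keep.any():
        raise ValueError(f"field has no data in {y0}-{y1}")
    vals = fld.values[keep]
    yaxis = fld.years[keep]
    finite = np.isfinite(vals)
    cnt = finite.sum(axis=0)
    tot = np.where(finite, vals, 0.0).sum(axis=0)
    mean = np.where(cnt > 0, tot / np.maximum(cnt, 1), np.nan)
    # a year contributes to a cell if it has at least one finite month there
    n_years = np.zeros(fld.grid.shape, dtype=int)
    for yr in np.unique(yaxis):
        n_years += np.any(finite[yaxis == yr], axis=0)
    mean = np.where(n_years >= min_years, mean, np.nan)
    return PeriodClimatology(mean, fld.grid, (y0, y1), n_years)


def trace_isotherm(
    clim: PeriodClimatology, temperature: float, band_mask: np.ndarray
) -> IsothermTrace:
    """First south-to-north crossing of the isotherm per longitude column."""
    if band_mask.shape != clim.grid.shape:
        raise ValueError("band_mask shape does not match the climatology grid")
    lats = clim.grid.lat_centers
    lons = clim.grid.lon_centers
    out_lons, out_lats, out_mult = [], [], []
    for j, lon in enumerate(lons):
        col = clim.values[:, j]
        use = band_mask[:, j] & np.isfinite(col)
        if use.sum() < 2:
            continue
        la = lats[use]
        d = col[use] - temperature
        sign_change = (d[:-1] == 0.0) | (np.sign(d[:-1]) != np.sign(d[1:]))
        hits = np.nonzero(sign_change)[0]
        if len(hits) == 0:
            continue
        i = hits[0]
        if d[i] == 0.0:
            lat_cross = la[i]
        else:
            lat_cross = la[i] + (la[i + 1] - la[i]) * d[i] / (d[i] - d[i + 1])
        out_lons.append(lon)
        out_lats.append(lat_cross)
        out_mult.append(len(hits) > 1)
    if not out_lons:
        raise ValueError(
            f"isotherm {temperature} degC has no crossing inside the band"
        )
    return IsothermTrace(
        temperature,
        np.asarray(out_lons),
        np.asarray(out_lats),
        np.asarray(out_mult, dtype=bool),
    )


def displacement(trace_a: IsothermTrace, trace_b: IsothermTrace) -> tuple[float, int]:
    """Mean signed meridional displacement (km) over common longitude columns.

    Positive when trace_b lies north of trace_a.  Returns (km, n_columns).
    """
    common, ia, ib = np.intersect1d(
        np.round(trace_a.lons, 9), np.round(trace_b.lons, 9), return_indices=True
    )
    if len(common) < 3:
        raise ValueError(f"need >=3 common longitude columns, got {len(common)}")
    dlat = trace_b.lats[ib] - trace_a.lats[ia]
    return float(np.mean(dlat) * KM_PER_DEG_LAT), len(common)


def anomaly_map(clim_b: PeriodClimatology, clim_a: PeriodClimatology) -> np.ndarray:
    """Cell-wise clim_b - clim_a (late minus early)."""
    if clim_b.grid != clim_a.grid:
        raise ValueError("climatologies are on different grids")
    return clim_b.values - clim_a.values


def shift_results(
    clim_a: PeriodClimatology,
    clim_b: PeriodClimatology,
    coastal_mask: np.ndarray,
    offshore_mask: np.ndarray,
    temperatures=DEFAULT_ISOTHERMS,
) -> list[IsothermShiftResult]:
    """Coastal and offshore displacement per isotherm between two periods.

    Isotherms that cannot be traced in both periods of a domain are reported
    as NaN for that domain rather than raising.
    """
    out = []
    for temp in temperatures:
        row = {}
        for name, mask in (("coastal", coastal_mask), ("offshore", offshore_mask)):
            try:
                ta = trace_isotherm(clim_a, temp, mask)
                tb = trace_isotherm(clim_b, temp, mask)
                km, n = displacement(ta, tb)
            except ValueError:
                km, n = np.nan, 0
            row[name] = (km, n)
        out.append(
            IsothermShiftResult(
                temp,
                row["coastal"][0],
                row["offshore"][0],
                row["coastal"][1],
                row["offshore"][1],
            )
        )
    return out
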