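"""Northern range limits, two-period shift with bootstrap inference, and
latitudinal partitioning of acoustic biomass.

Conventions
-----------
* Trawl tables are tidy DataFrames with columns ``year, date, lat, lon``
  plus one non-negative catch column per species; presence is catch > 0.
* Survey metadata is one row per survey year: ``coverage_north_limit``
  (deg N), ``has_biomass`` (bool), ``transect_spacing`` (deg lat).
* Degrees of latitude convert to km at 111.195 km/deg (meridional
  great-circle on the R=6371 km sphere).
* The per-decade normalisation divides by the difference of the period
  mean survey years (survey years are uneven, a hard 10 would not be
  reproducible).
* The bootstrap resamples whole survey years (the exchangeable unit)
  within each period, 10,000 times by default, and is deterministic for a
  fixed seed and invariant to record order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geo import KM_PER_DEG_LAT
from .series_trends import TrendResult, linear_trend

RESERVED_TRAWL_COLUMNS = ("year", "date", "lat", "lon")


def species_columns(trawls: pd.DataFrame) -> list[str]:
    return [c for c in trawls.columns if c not in RESERVED_TRAWL_COLUMNS]


@dataclass
class NorthernLimitSeries:
    """Per-year northern range edge of one species."""

    species: str
    table: pd.DataFrame  # index: year; columns: limit, censored

    def usable(self, include_censored: bool = False) -> pd.DataFrame:
        t = self.table.dropna(subset=["limit"])
        if not include_censored:
            t = t[~t["censored"]]
        return t


@dataclass(frozen=True)
class ShiftEstimate:
    species: str
    mean_limit_a: float
    mean_limit_b: float
    mean_year_a: float
    mean_year_b: float
    shift_km_per_decade: float
    ci_low: float | None = None
    ci_high: float | None = None
    p_value: float | None = None
    n_boot: int | None = None
    seed: int | None = None


@dataclass(frozen=True)
class BootstrapResult:
    delta: float
    ci_low: float
    ci_high: float
    p_value: float
    n_boot: int
    seed: int


def northern_limit(
    trawls: pd.DataFrame,
    species: str,
    year: int,
    meta: pd.DataFrame,
) -> tuple[float, bool] | None:
    """Max presence latitude of `species` in `year`; None if absent all year.

    The limit is censored when it falls within one transect spacing of the
    survey's coverage_north_limit, i.e. the true edge may lie beyond the
    sampled domain.
    """
    rows = trawls[trawls["year"] == year]
    if len(rows) == 0:
        raise ValueError(f"no trawl records for year {year}")
    present = rows[rows[species] > 0]
    if len(present) == 0:
        return None
    limit = float(present["lat"].max())
    coverage = float(meta.loc[year, "coverage_north_limit"])
    spacing = float(meta.loc[year, "transect_spacing"])
    censored = (coverage - limit) <= spacing
    return limit, censored


def northern_limit_series(
    trawls: pd.DataFrame, species: str, meta: pd.DataFrame
) -> NorthernLimitSeries:
    """Yearly northern limits over every survey year present in the trawls."""
    years = sorted(trawls["year"].unique())
    recs = []
    for yr in years:
        res = northern_limit(trawls, species, yr, meta)
        if res is None:
            recs.append((yr, np.nan, False))
        else:
            recs.append((yr, res[0], res[1]))
    table = pd.DataFrame(recs, columns=["year", "limit", "censored"]).set_index("year")
    return NorthernLimitSeries(species, table)


def _period_arrays(limits, period, include_censored):
    t = limits.usable(include_censored=include_censored)
    sel = t[(t.index >= period[0]) & (t.index <= period[1])]
    return sel.index.to_numpy(dtype=float), sel["limit"].to_numpy(dtype=float)


def period_shift(
    limits: NorthernLimitSeries,
    period_a: tuple[int, int],
    period_b: tuple[int, int],
    include_censored: bool = False,
) -> ShiftEstimate:
    """Difference of period-mean limits, expressed in km per decade."""
    ya, la = _period_arrays(limits, period_a, include_censored)
    yb, lb = _period_arrays(limits, period_b, include_censored)
    if len(la) < 2 or len(lb) < 2:
        raise ValueError(
            f"{limits.species}: need >=2 usable limits per period "
            f"(got {len(la)} and {len(lb)})"
        )
    km = (lb.mean() - la.mean()) * KM_PER_DEG_LAT
    # |dt| so that swapping the periods flips the sign of the estimate
    dt_years = abs(yb.mean() - ya.mean())
    return ShiftEstimate(
        species=limits.species,
        mean_limit_a=float(la.mean()),
        mean_limit_b=float(lb.mean()),
        mean_year_a=float(ya.mean()),
        mean_year_b=float(yb.mean()),
        shift_km_per_decade=float(km / dt_years * 10.0),
    )


def _bootstrap_two_sample(
    values_a, years_a, values_b, years_b, statistic, n_boot, seed
):
    """Resample whole years with replacement within each group.

    `statistic(va, ya, vb, yb)` is evaluated on (n_boot, n) index matrices;
    it must accept 2-D arrays and reduce along axis 1.
    """
    rng = np.random.default_rng(seed)
    na, nb = len(values_a), len(values_b)
    ia = rng.integers(0, na, size=(n_boot, na))
    ib = rng.integers(0, nb, size=(n_boot, nb))
    stat = statistic(values_a[ia], years_a[ia], values_b[ib], years_b[ib])
    ci_low, ci_high = np.percentile(stat, [2.5, 97.5])
    n_le = int(np.sum(stat <= 0.0))
    n_ge = int(np.sum(stat >= 0.0))
    p = 2.0 * min(n_le, n_ge) / n_boot
    p = min(1.0, max(p, 2.0 / n_boot))
    return stat, float(ci_low), float(ci_high), float(p)


def bootstrap_shift(
    limits: NorthernLimitSeries,
    period_a: tuple[int, int],
    period_b: tuple[int, int],
    n_boot: int = 10_000,
    seed: int = 0,
    include_censored: bool = False,
) -> ShiftEstimate:
    """period_shift with a percentile bootstrap CI and two-sided p.

    Years (with their limits) are resampled with replacement within each
    period and the full km-per-decade statistic is recomputed each time.
    """
    point = period_shift(limits, period_a, period_b, include_censored)
    ya, la = _period_arrays(limits, period_a, include_censored)
    yb, lb = _period_arrays(limits, period_b, include_censored)
    # sort by year so results are invariant to record order
    oa, ob = np.argsort(ya), np.argsort(yb)
    ya, la, yb, lb = ya[oa], la[oa], yb[ob], lb[ob]
    # the per-decade denominator stays at its point-estimate value: the
    # bootstrap measures uncertainty in the limits, not in the survey design
    dt = abs(point.mean_year_b - point.mean_year_a)

    def stat(la_s, ya_s, lb_s, yb_s):
        km = (lb_s.mean(axis=1) - la_s.mean(axis=1)) * KM_PER_DEG_LAT
        return km / dt * 10.0

    _, ci_low, ci_high, p = _bootstrap_two_sample(la, ya, lb, yb, stat, n_boot, seed)
    return ShiftEstimate(
        species=point.species,
        mean_limit_a=point.mean_limit_a,
        mean_limit_b=point.mean_limit_b,
        mean_year_a=point.mean_year_a,
        mean_year_b=point.mean_year_b,
        shift_km_per_decade=point.shift_km_per_decade,
        ci_low=ci_low,
        ci_high=ci_high,
        p_value=p,
        n_boot=n_boot,
        seed=seed,
    )


def limit_trend(
    limits: NorthernLimitSeries, include_censored: bool = False
) -> TrendResult:
    """Linear trend of the yearly northern limit in km per decade."""
    t = limits.usable(include_censored=include_censored)
    if len(t) < 3:
        raise ValueError(f"{limits.species}: need >=3 yearly limits for a trend")
    return linear_trend(t.index.to_numpy(), t["limit"].to_numpy() * KM_PER_DEG_LAT)


def hovmoller(bins: pd.DataFrame, years=None) -> pd.DataFrame:
    """Latitude-bin x year matrix of summed biomass.

    `bins` columns: year, lat_lo, value.  Rows are bin lower edges sorted
    south to north, columns years; years listed in `years` but absent from
    `bins` (e.g. surveys without a biomass estimate) appear as NaN columns.
    """
    mat = bins.pivot_table(
        index="lat_lo", columns="year", values="value", aggfunc="sum"
    ).sort_index()
    if years is not None:
        mat = mat.reindex(columns=sorted(years))
    return mat


def fraction_north(bins: pd.DataFrame, boundary_lat: float = 21.0) -> pd.Series:
    """Yearly fraction of biomass in bins with lat_lo >= boundary_lat."""
    total = bins.groupby("year")["value"].sum()
    north = (
        bins[bins["lat_lo"] >= boundary_lat].groupby("year")["value"].sum()
    ).reindex(total.index, fill_value=0.0)
    frac = north / total
    frac[total == 0.0] = np.nan
    frac.name = "fraction_north"
    return frac


def bootstrap_fraction(
    fractions: pd.Series,
    period_a: tuple[int, int],
    period_b: tuple[int, int],
    n_boot: int = 10_000,
    seed: int = 0,
) -> BootstrapResult:
    """Bootstrap test of the change in the yearly fraction between periods."""
    f = fractions.dropna()
    years = f.index.to_numpy(dtype=float)
    vals = f.to_numpy(dtype=float)
    in_a = (years >= period_a[0]) & (years <= period_a[1])
    in_b = (years >= period_b[0]) & (years <= period_b[1])
    fa, fb = vals[in_a], vals[in_b]
    ya, yb = years[in_a], years[in_b]
    if len(fa) < 2 or len(fb) < 2:
        raise ValueError("need >=2 yearly fractions per period")
    oa, ob = np.argsort(ya), np.argsort(yb)
    fa, ya, fb, yb = fa[oa], ya[oa], fb[ob], yb[ob]

    def stat(a, _ya, b, _yb):
        return b.mean(axis=1) - a.mean(axis=1)

    _, ci_low, ci_high, p = _bootstrap_two_sample(fa, ya, fb, yb, stat, n_boot, seed)
    return BootstrapResult(
        delta=float(fb.mean() - fa.mean()),
        ci_low=ci_low,
        ci_high=ci_high,
        p_value=p,
        n_boot=n_boot,
        seed=seed,
    )
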