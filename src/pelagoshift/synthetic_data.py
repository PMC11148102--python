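"""Self-consistent synthetic world with recorded ground truth.

Generates a coastal domain, monthly environmental fields (SST 1982-2021,
wind 1988-2021, two overlapping chlorophyll sensors 1998-2021) and annual
trawl/acoustic surveys (1995-2006, 2011, 2015), every recoverable parameter
of which is written to a :class:`TruthRecord`.

Randomness: one substream per component (sst, wind, chl, surveys), spawned
in a fixed order from the master seed, so e.g. adding a species never
perturbs the SST noise.  All outputs are bit-reproducible from
(WorldConfig, seed).

The logistic occupancy model linking a species' true northern limit to
presence at a station is a stand-in: the source surveys provide no
quantitative occupancy model, so the edge is softened by a configurable
steepness (step function in the steepness -> 0 limit).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import geo
from .geo import KM_PER_DEG_LAT, CoastGeometry, GridField, GridSpec

SURVEY_YEARS_DEFAULT = tuple(range(1995, 2007)) + (2011, 2015)


# --------------------------------------------------------------------------
# configuration blocks


@dataclass(frozen=True)
class CoastConfig:
    lon_at_lat_min: float = -14.8  # coastline longitude at the grid's lat_min
    lon_slope_per_deg: float = -0.25  # coast drifts west going north
    isobath_offset_km: float = 30.0  # 200 m isobath sits this far offshore
    vertex_spacing_deg: float = 0.25


@dataclass(frozen=True)
class SSTConfig:
    mean_at_12n: float = 27.0  # degC
    gradient_per_deg: float = 0.45  # degC per deg lat, cooling northward
    seasonal_amplitude: float = 2.0  # degC
    peak_month: int = 9
    trend_per_decade: float | tuple = 0.35  # scalar or ((lat_lo, lat_hi, val), ...)
    step_year: int | None = None
    step_degc: float = 0.0
    cooling_max: float = 3.0  # degC at the coast
    cooling_efold_km: float = 50.0
    cooling_peak_month: int = 7
    ar1_phi: float = 0.6
    noise_sigma: float = 0.3  # marginal (stationary) sd, degC
    start_year: int = 1982
    end_year: int = 2021


@dataclass(frozen=True)
class WindConfig:
    mean_speed: float = 6.0  # m s^-1, equatorward alongshore
    trend_per_decade: float | tuple = 0.2
    seasonal_amplitude: float = 1.0
    peak_month: int = 7
    ar1_phi: float = 0.4
    noise_sigma: float = 0.5
    start_year: int = 1988
    end_year: int = 2021


@dataclass(frozen=True)
class ChlConfig:
    background: float = 0.5  # mg m^-3
    enrichment: float = 5.0  # mg m^-3 at unit normalized upwelling proxy
    log_noise_sigma: float = 0.15  # sd of ln-multiplicative sensor noise
    bias_a: float = 1.0  # multiplicative sensor biases
    bias_b: float = 1.3
    span_a: tuple[int, int] = (1998, 2010)
    span_b: tuple[int, int] = (2003, 2021)
    proxy_efold_km: float = 50.0
    proxy_peak_month: int = 7
    start_year: int = 1998
    end_year: int = 2021


@dataclass(frozen=True)
class SpeciesConfig:
    initial_limit: float = 19.0  # deg N at the first survey year
    drift_km_per_decade: float = 180.0
    occupancy_steepness: float = 0.35  # deg lat; 0 -> hard step at the limit
    detection_probability: float = 0.95
    nasc_log_mean: float = math.log(100.0)
    nasc_log_sigma: float = 1.0


@dataclass(frozen=True)
class SurveyConfig:
    years: tuple[int, ...] = SURVEY_YEARS_DEFAULT
    month: int = 11
    transect_spacing: float = 0.5  # deg lat
    stations_per_transect: int = 5
    southern_limit: float = 12.0
    coverage_north_limit: float = 29.0
    coverage_overrides: tuple[tuple[int, float], ...] = ((2005, 26.3),)
    no_biomass_years: tuple[int, ...] = (2011,)
    station_offsets_km: tuple[float, ...] = (10.0, 25.0, 45.0, 65.0, 90.0)


def _default_species() -> tuple[tuple[str, SpeciesConfig], ...]:
    return (
        ("drifter", SpeciesConfig()),
        ("resident", SpeciesConfig(initial_limit=21.5, drift_km_per_decade=0.0)),
    )


@dataclass(frozen=True)
class WorldConfig:
    grid: GridSpec = field(
        default_factory=lambda: GridSpec(10.0, 32.0, -22.0, -10.0, 0.25)
    )
    coast: CoastConfig = field(default_factory=CoastConfig)
    sst: SSTConfig = field(default_factory=SSTConfig)
    wind: WindConfig = field(default_factory=WindConfig)
    chl: ChlConfig = field(default_factory=ChlConfig)
    species: tuple[tuple[str, SpeciesConfig], ...] = field(
        default_factory=_default_species
    )
    surveys: SurveyConfig = field(default_factory=SurveyConfig)
    boundary_lat: float = 21.0
    strip_width_km: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        for cfg, names in (
            (self.sst, ("noise_sigma",)),
            (self.wind, ("noise_sigma",)),
            (self.chl, ("log_noise_sigma",)),
        ):
            for n in names:
                if getattr(cfg, n) < 0:
                    raise ValueError(f"{n} must be >= 0")
        for cfg in (self.sst, self.wind):
            if not 0.0 <= cfg.ar1_phi < 1.0:
                raise ValueError("AR(1) phi must be in [0, 1)")
        for yr in self.surveys.years:
            if not 1982 <= yr <= 2021:
                raise ValueError(f"survey year {yr} outside [1982, 2021]")
        for _, sp in self.species:
            if not np.isfinite(sp.drift_km_per_decade):
                raise ValueError("species drift must be finite")


@dataclass
class TruthRecord:
    """Ground truth of everything the analysis pipeline should recover."""

    band_trends: dict  # variable -> {band_id: slope per decade}
    species_drift: dict  # species -> km per decade
    species_limits: dict  # species -> {year: true limit deg N}
    fraction_north: dict  # species -> {year: expected biomass fraction}
    boundary_lat: float
    chl_bias_ratio: float  # bias_b / bias_a


@dataclass
class World:
    config: WorldConfig
    coast: CoastGeometry
    sst: GridField
    wind_u: GridField
    wind_v: GridField
    chl_a: GridField
    chl_b: GridField
    trawls: pd.DataFrame
    acoustic_bins: pd.DataFrame
    survey_meta: pd.DataFrame
    truth: TruthRecord
    distances_km: np.ndarray  # distance-to-coast field, NaN on land


# --------------------------------------------------------------------------
# helpers


def _monthly_index(y0: int, y1: int) -> pd.PeriodIndex:
    return pd.period_range(f"{y0}-01", f"{y1}-12", freq="M")


def _time_fraction_years(time: pd.PeriodIndex, origin_year: int) -> np.ndarray:
    return np.asarray(
        (time.year - origin_year) + (time.month - 0.5) / 12.0, dtype=float
    )


def _trend_at_lat(trend, lats: np.ndarray) -> np.ndarray:
    """Scalar or piecewise-by-latitude trend (per decade) per latitude."""
    if np.isscalar(trend):
        return np.full_like(lats, float(trend))
    out = np.zeros_like(lats)
    for lo, hi, val in trend:
        out[(lats >= lo) & (lats < hi)] = val
    return out


def _ar1_noise(rng, phi: float, sigma: float, shape: tuple) -> np.ndarray:
    """Stationary AR(1) noise along axis 0 with marginal sd = sigma."""
    if sigma == 0.0:
        return np.zeros(shape)
    eps_sd = sigma * math.sqrt(1.0 - phi * phi)
    out = np.empty(shape)
    out[0] = rng.normal(0.0, sigma, size=shape[1:])
    for t in range(1, shape[0]):
        out[t] = phi * out[t - 1] + rng.normal(0.0, eps_sd, size=shape[1:])
    return out


def _season(months: np.ndarray, peak_month: int) -> np.ndarray:
    return np.cos(2.0 * np.pi * (months - peak_month) / 12.0)


def _season_window(months: np.ndarray, peak_month: int) -> np.ndarray:
    """Raised-cosine seasonal weight in [0, 1], peaking at peak_month."""
    return 0.5 * (1.0 + np.cos(2.0 * np.pi * (months - peak_month) / 12.0))


def build_coast(config: WorldConfig) -> CoastGeometry:
    """Near-meridional coastline with the isobath offset a fixed km west."""
    g, c = config.grid, config.coast
    lats = np.arange(g.lat_min, g.lat_max + 1e-9, c.vertex_spacing_deg)
    coast_lon = c.lon_at_lat_min + c.lon_slope_per_deg * (lats - g.lat_min)
    iso_lon = coast_lon - c.isobath_offset_km / (
        KM_PER_DEG_LAT * np.cos(np.radians(lats))
    )
    return CoastGeometry(
        np.column_stack([lats, coast_lon]), np.column_stack([lats, iso_lon])
    )


# --------------------------------------------------------------------------
# field generators


def generate_sst(
    config: WorldConfig,
    coast: CoastGeometry,
    rng=None,
    distances: np.ndarray | None = None,
) -> GridField:
    """Monthly SST: gradient + season + trend (+ step) + coastal cooling + AR(1)."""
    s = config.sst
    grid = config.grid
    if distances is None:
        distances = geo.distance_to_coast_field(grid, coast)
    time = _monthly_index(s.start_year, s.end_year)
    months = np.asarray(time.month)
    tfrac = _time_fraction_years(time, s.start_year)
    lats = grid.lat_centers
    base = s.mean_at_12n - s.gradient_per_deg * (lats - 12.0)  # (nlat,)
    trend = _trend_at_lat(s.trend_per_decade, lats) / 10.0  # per year
    vals = (
        base[None, :, None]
        + (s.seasonal_amplitude * _season(months, s.peak_month))[:, None, None]
        + trend[None, :, None] * tfrac[:, None, None]
    )
    if s.step_year is not None:
        vals = vals + s.step_degc * (np.asarray(time.year) >= s.step_year)[
            :, None, None
        ]
    cool_space = np.exp(-distances / s.cooling_efold_km)  # NaN on land
    cool_season = _season_window(months, s.cooling_peak_month)
    vals = vals - s.cooling_max * cool_season[:, None, None] * cool_space[None, :, :]
    if rng is not None and s.noise_sigma > 0:
        vals = vals + _ar1_noise(rng, s.ar1_phi, s.noise_sigma, vals.shape)
    return GridField("sst", "degC", grid, time, vals)


def generate_wind(
    config: WorldConfig, coast: CoastGeometry, rng=None
) -> tuple[GridField, GridField]:
    """Equatorward alongshore wind decomposed to (u, v) from the isobath."""
    w = config.wind
    grid = config.grid
    time = _monthly_index(w.start_year, w.end_year)
    months = np.asarray(time.month)
    tfrac = _time_fraction_years(time, w.start_year)
    lats = grid.lat_centers
    trend = _trend_at_lat(w.trend_per_decade, lats) / 10.0
    speed = (
        np.full(lats.shape, w.mean_speed)[None, :, None]
        + (w.seasonal_amplitude * _season(months, w.peak_month))[:, None, None]
        + trend[None, :, None] * tfrac[:, None, None]
    )
    speed = np.broadcast_to(speed, (len(time),) + grid.shape).copy()
    if rng is not None and w.noise_sigma > 0:
        speed = speed + _ar1_noise(rng, w.ar1_phi, w.noise_sigma, speed.shape)
    theta = geo.isobath_angle(coast, lats)  # poleward tangent
    u = speed * (-np.cos(theta))[None, :, None]
    v = speed * (-np.sin(theta))[None, :, None]
    return (
        GridField("wind_u", "m s-1", grid, time, u),
        GridField("wind_v", "m s-1", grid, time, v),
    )


def upwelling_proxy_field(
    config: WorldConfig,
    coast: CoastGeometry,
    distances: np.ndarray | None = None,
) -> GridField:
    """Deterministic coastal-upwelling structure proxy in [0, 1]."""
    c = config.chl
    grid = config.grid
    if distances is None:
        distances = geo.distance_to_coast_field(grid, coast)
    time = _monthly_index(c.start_year, c.end_year)
    months = np.asarray(time.month)
    space = np.exp(-distances / c.proxy_efold_km)
    vals = _season_window(months, c.proxy_peak_month)[:, None, None] * space[None, :, :]
    return GridField("upwelling_proxy", "1", grid, time, vals)


def generate_chl(
    config: WorldConfig, upwelling_proxy: GridField, rng=None
) -> tuple[GridField, GridField]:
    """Two biased sensor views of the same truth chlorophyll field.

    truth = background + enrichment * normalized proxy; each sensor is the
    truth times a multiplicative bias and log-normal noise, defined only on
    its own year span (NaN elsewhere).
    """
    c = config.chl
    proxy = upwelling_proxy.values
    peak = np.nanmax(proxy)
    norm = proxy / peak if peak > 0 else proxy
    truth = c.background + c.enrichment * norm
    time = upwelling_proxy.time
    years = np.asarray(time.year)

    def sensor(bias, span, stream):
        vals = truth * bias
        if stream is not None and c.log_noise_sigma > 0:
            vals = vals * np.exp(
                stream.normal(0.0, c.log_noise_sigma, size=vals.shape)
            )
        outside = (years < span[0]) | (years > span[1])
        vals = vals.copy()
        vals[outside] = np.nan
        return vals

    a = sensor(c.bias_a, c.span_a, rng)
    b = sensor(c.bias_b, c.span_b, rng)
    grid = upwelling_proxy.grid
    return (
        GridField("chl_sensor_a", "mg m-3", grid, time, a),
        GridField("chl_sensor_b", "mg m-3", grid, time, b),
    )


# --------------------------------------------------------------------------
# surveys


def true_limit(sp: SpeciesConfig, year: int, first_year: int) -> float:
    """True northern limit (deg N) of a drifting species in a given year."""
    drift_deg_per_year = sp.drift_km_per_decade / KM_PER_DEG_LAT / 10.0
    return sp.initial_limit + drift_deg_per_year * (year - first_year)


def _occupancy(sp: SpeciesConfig, lat: np.ndarray, limit: float) -> np.ndarray:
    """P(present at a station) = detection * logistic((limit - lat)/steepness)."""
    if sp.occupancy_steepness == 0.0:
        return sp.detection_probability * (lat < limit).astype(float)
    z = (limit - lat) / sp.occupancy_steepness
    return sp.detection_probability / (1.0 + np.exp(-np.clip(z, -500, 500)))


def _coverage_for_year(sv: SurveyConfig, year: int) -> float:
    return dict(sv.coverage_overrides).get(year, sv.coverage_north_limit)


def _transect_lats(sv: SurveyConfig, year: int) -> np.ndarray:
    coverage = _coverage_for_year(sv, year)
    lats = np.arange(sv.southern_limit, coverage + 1e-9, sv.transect_spacing)
    if len(lats) == 0:
        raise ValueError(
            f"survey {year}: coverage limit {coverage} is south of all transects"
        )
    return lats


def generate_surveys(
    config: WorldConfig, coast: CoastGeometry, rng
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate trawl stations, presence/NASC catches and acoustic bins.

    Stations sit on zonal transects every transect_spacing deg of latitude
    up to the year's coverage limit, at fixed offshore offsets.  Iteration
    order (years, transects, stations, species by name) is fixed so draws
    are reproducible and independent of table ordering.
    """
    sv = config.surveys
    first_year = sv.years[0]
    species = sorted(config.species, key=lambda kv: kv[0])
    names = [n for n, _ in species]
    rows = []
    for year in sv.years:
        lats = _transect_lats(sv, year)
        date = f"{year}-{sv.month:02d}-15"
        for lat in lats:
            coast_lon = coast.lon_at(lat, "coastline")
            for off_km in sv.station_offsets_km[: sv.stations_per_transect]:
                lon = coast_lon - off_km / (KM_PER_DEG_LAT * math.cos(math.radians(lat)))
                catches = []
                for name, sp in species:
                    limit = true_limit(sp, year, first_year)
                    p = float(_occupancy(sp, np.asarray(lat), limit))
                    present = rng.random() < p
                    nasc = (
                        float(rng.lognormal(sp.nasc_log_mean, sp.nasc_log_sigma))
                        if present
                        else 0.0
                    )
                    catches.append(nasc)
                rows.append([year, date, float(lat), float(lon)] + catches)
    trawls = pd.DataFrame(rows, columns=["year", "date", "lat", "lon"] + names)

    spacing = sv.transect_spacing
    bin_lo = np.floor(trawls["lat"] / 0.5) * 0.5
    long_rows = []
    for name in names:
        g = trawls.assign(lat_lo=bin_lo).groupby(["year", "lat_lo"])[name].sum()
        for (year, lo), val in g.items():
            if year in sv.no_biomass_years:
                continue
            long_rows.append((name, int(year), float(lo), float(val)))
    bins = pd.DataFrame(long_rows, columns=["species", "year", "lat_lo", "value"])

    meta = pd.DataFrame(
        {
            "year": list(sv.years),
            "coverage_north_limit": [_coverage_for_year(sv, y) for y in sv.years],
            "has_biomass": [y not in sv.no_biomass_years for y in sv.years],
            "transect_spacing": spacing,
        }
    ).set_index("year")
    return trawls, bins, meta


def _truth_fractions(config: WorldConfig) -> dict:
    """Expected biomass fraction north of the boundary, per species and year."""
    sv = config.surveys
    first_year = sv.years[0]
    out = {}
    for name, sp in config.species:
        per_year = {}
        for year in sv.years:
            lats = _transect_lats(sv, year)
            limit = true_limit(sp, year, first_year)
            p = _occupancy(sp, lats, limit)
            total = p.sum()
            north = p[lats >= config.boundary_lat].sum()
            per_year[year] = float(north / total) if total > 0 else float("nan")
        out[name] = per_year
    return out


# --------------------------------------------------------------------------
# world assembly


def _noise_free(config: WorldConfig) -> WorldConfig:
    return replace(
        config,
        sst=replace(config.sst, noise_sigma=0.0),
        wind=replace(config.wind, noise_sigma=0.0),
        chl=replace(config.chl, log_noise_sigma=0.0),
    )


def _realized_band_trends(config: WorldConfig, coast, distances, mask) -> dict:
    """Band trends of the deterministic (noise-free) world, per decade."""
    from . import series_trends, upwelling

    quiet = _noise_free(config)
    out = {}
    lat_centers = config.grid.lat_centers
    bands = [
        b
        for b in geo.DEFAULT_BANDS
        if (mask & ((lat_centers >= b.lat_lo) & (lat_centers < b.lat_hi))[:, None]).any()
    ]
    sst = generate_sst(quiet, coast, rng=None, distances=distances)
    u, v = generate_wind(quiet, coast, rng=None)
    _, uw_series = upwelling.index_field_and_bands(u, v, coast, mask, bands=bands)
    proxy = upwelling_proxy_field(quiet, coast, distances=distances)
    chl_a, chl_b = generate_chl(quiet, proxy, rng=None)
    speed = GridField(
        "wind_speed", "m s-1", u.grid, u.time, np.hypot(u.values, v.values)
    )
    for var, fld in (("sst", sst), ("wind_speed", speed)):
        out[var] = {}
        for band in geo.DEFAULT_BANDS:
            try:
                s = geo.area_series(fld, mask, band)
            except ValueError:  # band empty on coarse test grids
                continue
            yearly = series_trends.annual_mean(
                series_trends.MonthlySeries(var, "", band.id, s)
            ).dropna()
            out[var][band.id] = series_trends.linear_trend(
                yearly.index.to_numpy(), yearly.to_numpy()
            ).slope_per_decade
    out["upwelling_index"] = {}
    for band_id, ms in uw_series.items():
        yearly = series_trends.annual_mean(ms).dropna()
        out["upwelling_index"][band_id] = series_trends.linear_trend(
            yearly.index.to_numpy(), yearly.to_numpy()
        ).slope_per_decade
    # merged truth chlorophyll (sensor A truth equals background+enrichment)
    out["chl"] = {}
    truth_chl = GridField(
        "chl", "mg m-3", chl_a.grid, chl_a.time,
        np.where(np.isfinite(chl_a.values), chl_a.values, chl_b.values / config.chl.bias_b * config.chl.bias_a),
    )
    for band in geo.DEFAULT_BANDS:
        try:
            s = geo.area_series(truth_chl, mask, band)
        except ValueError:
            continue
        yearly = series_trends.annual_mean(
            series_trends.MonthlySeries("chl", "", band.id, s)
        ).dropna()
        out["chl"][band.id] = series_trends.linear_trend(
            yearly.index.to_numpy(), yearly.to_numpy()
        ).slope_per_decade
    return out


def build_world(config: WorldConfig, with_truth_trends: bool = True) -> World:
    """Generate the full synthetic world deterministically from the seed."""
    ss = np.random.SeedSequence(config.seed)
    streams = {
        name: np.random.default_rng(child)
        for name, child in zip(("sst", "wind", "chl", "surveys"), ss.spawn(4))
    }
    coast = build_coast(config)
    distances = geo.distance_to_coast_field(config.grid, coast)
    mask = geo.coastal_mask(
        config.grid, coast, config.strip_width_km, distances=distances
    )
    sst = generate_sst(config, coast, rng=streams["sst"], distances=distances)
    wind_u, wind_v = generate_wind(config, coast, rng=streams["wind"])
    proxy = upwelling_proxy_field(config, coast, distances=distances)
    chl_a, chl_b = generate_chl(config, proxy, rng=streams["chl"])
    trawls, bins, meta = generate_surveys(config, coast, streams["surveys"])

    first_year = config.surveys.years[0]
    limits = {
        name: {yr: true_limit(sp, yr, first_year) for yr in config.surveys.years}
        for name, sp in config.species
    }
    truth = TruthRecord(
        band_trends=(
            _realized_band_trends(config, coast, distances, mask)
            if with_truth_trends
            else {}
        ),
        species_drift={name: sp.drift_km_per_decade for name, sp in config.species},
        species_limits=limits,
        fraction_north=_truth_fractions(config),
        boundary_lat=config.boundary_lat,
        chl_bias_ratio=config.chl.bias_b / config.chl.bias_a,
    )
    return World(
        config=config,
        coast=coast,
        sst=sst,
        wind_u=wind_u,
        wind_v=wind_v,
        chl_a=chl_a,
        chl_b=chl_b,
        trawls=trawls,
        acoustic_bins=bins,
        survey_meta=meta,
        truth=truth,
        distances_km=distances,
    )
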