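"""Wind stress and the isobath-oriented Ekman upwelling index.

The index is the offshore component of the Ekman transport per metre of
coast (m^2 s^-1), computed cell-wise with the alongshore direction taken
from the 200 m isobath tangent at each cell's latitude.  Positive values
are upwelling-favourable (offshore transport).

The order of operations matters: stress is quadratic in wind, so the index
is computed per cell and then area-averaged, not from band-mean winds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import geo
from .series_trends import MonthlySeries


@dataclass(frozen=True)
class PhysicalConstants:
    """Bulk-formula and rotation constants (config-overridable, logged)."""

    rho_air: float = 1.22  # kg m^-3
    drag_coefficient: float = 1.3e-3  # dimensionless
    rho_seawater: float = 1025.0  # kg m^-3
    earth_rotation: float = 7.2921e-5  # rad s^-1

    def __post_init__(self) -> None:
        for name in ("rho_air", "drag_coefficient", "rho_seawater", "earth_rotation"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


DEFAULT_CONSTANTS = PhysicalConstants()

#: Equatorial guard: Ekman theory blows up as f -> 0.
MIN_ABS_LATITUDE = 5.0


def wind_stress(u, v, constants: PhysicalConstants = DEFAULT_CONSTANTS):
    """Bulk-formula stress tau = rho_a C_d |W| (u, v), N m^-2."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    speed = np.hypot(u, v)
    k = constants.rho_air * constants.drag_coefficient * speed
    return k * u, k * v


def coriolis(lat, constants: PhysicalConstants = DEFAULT_CONSTANTS):
    """Coriolis parameter f = 2 Omega sin(lat), s^-1."""
    lat = np.asarray(lat, dtype=float)
    if np.any(np.abs(lat) < MIN_ABS_LATITUDE):
        raise ValueError(
            f"equatorial singularity: |lat| must be >= {MIN_ABS_LATITUDE} deg"
        )
    f = 2.0 * constants.earth_rotation * np.sin(np.radians(lat))
    return float(f) if f.ndim == 0 else f


def ekman_index(tau_x, tau_y, isobath_angle, lat,
                constants: PhysicalConstants = DEFAULT_CONSTANTS):
    """Offshore Ekman transport per metre of coast, m^2 s^-1.

    With poleward alongshore tangent t = (cos th, sin th) and offshore
    normal n = (-sin th, cos th) (ocean to the left of t), the transport
    M = (tau_y, -tau_x) / (rho_w f) projected on n gives
    index = -(tau_x cos th + tau_y sin th) / (rho_w f).
    """
    f = coriolis(lat, constants)
    th = np.asarray(isobath_angle, dtype=float)
    tau_x = np.asarray(tau_x, dtype=float)
    tau_y = np.asarray(tau_y, dtype=float)
    idx = -(tau_x * np.cos(th) + tau_y * np.sin(th)) / (constants.rho_seawater * f)
    return float(idx) if np.ndim(idx) == 0 else idx


def index_field_and_bands(
    u_field: geo.GridField,
    v_field: geo.GridField,
    coast: geo.CoastGeometry,
    mask: np.ndarray,
    bands=geo.DEFAULT_BANDS,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
):
    """Cell-wise upwelling index inside the coastal strip + band series.

    Returns ``(index_field, {band_id: MonthlySeries})``.  The isobath angle
    is evaluated at each cell's latitude; cells outside the mask are NaN.
    """
    if u_field.values.shape != v_field.values.shape:
        raise ValueError("u and v fields must share grid and time axis")
    grid = u_field.grid
    tau_x, tau_y = wind_stress(u_field.values, v_field.values, constants)
    theta = geo.isobath_angle(coast, grid.lat_centers)  # (n_lat,)
    f = coriolis(grid.lat_centers, constants)
    idx = -(tau_x * np.cos(theta)[None, :, None]
            + tau_y * np.sin(theta)[None, :, None]) / (
        constants.rho_seawater * f[None, :, None]
    )
    idx = np.where(mask[None, :, :], idx, np.nan)
    index_field = geo.GridField(
        "upwelling_index", "m2 s-1", grid, u_field.time, idx
    )
    series = {}
    for band in bands:
        s = geo.area_series(index_field, mask, band)
        series[band.id] = MonthlySeries("upwelling_index", "m2 s-1", band.id, s)
    return index_field, series


def to_display_units(index_m2_s: np.ndarray) -> np.ndarray:
    """Convert m^2 s^-1 (per m of coast) to m^3 s^-1 per 100 m of coast."""
    return np.asarray(index_m2_s, dtype=float) * 100.0
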