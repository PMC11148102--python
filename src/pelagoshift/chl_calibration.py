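"""Cross-calibration and merging of two overlapping chlorophyll sensors.

A log10 affine map is fitted on the paired overlap months at the band-series
level (per-pixel correction is out of scope here), then the non-reference
sensor is corrected and the two series concatenated at the switch year.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .series_trends import MonthlySeries

MIN_OVERLAP_PAIRS = 24


@dataclass
class SensorSeries:
    """One sensor's monthly chlorophyll series (mg m^-3, strictly positive)."""

    sensor_id: str
    series: MonthlySeries
    span: tuple[int, int]  # (first_year, last_year) valid span

    def __post_init__(self) -> None:
        vals = self.series.data.dropna()
        if (vals <= 0).any():
            raise ValueError(f"sensor {self.sensor_id}: chlorophyll must be > 0")


def fit_cross_calibration(
    ref: SensorSeries, other: SensorSeries, overlap: tuple[int, int]
) -> tuple[float, float]:
    """OLS fit log10(ref) = b0 + b1 log10(other) on paired overlap months."""
    y0, y1 = overlap
    r = ref.series.data.dropna()
    o = other.series.data.dropna()
    r = r[(r.index.year >= y0) & (r.index.year <= y1)]
    o = o[(o.index.year >= y0) & (o.index.year <= y1)]
    paired = pd.concat([r, o], axis=1, join="inner", keys=["ref", "other"])
    if len(paired) < MIN_OVERLAP_PAIRS:
        raise ValueError(
            f"need >={MIN_OVERLAP_PAIRS} paired overlap months, got {len(paired)}"
        )
    x = np.log10(paired["other"].to_numpy())
    y = np.log10(paired["ref"].to_numpy())
    if np.ptp(x) == 0.0:
        # degenerate constant series: pure offset correction
        return float(np.mean(y - x)), 1.0
    fit = stats.linregress(x, y)
    return float(fit.intercept), float(fit.slope)


def apply_and_merge(
    ref: SensorSeries,
    other: SensorSeries,
    coeffs: tuple[float, float],
    switch_year: int = 2011,
) -> MonthlySeries:
    """Correct `other` through 10^(b0 + b1 log10) and splice at switch_year.

    The merged record uses the reference sensor before switch_year and the
    corrected other sensor from switch_year on; positivity is preserved by
    construction.
    """
    b0, b1 = coeffs
    o = other.series.data.dropna()
    corrected = pd.Series(10.0 ** (b0 + b1 * np.log10(o.to_numpy())), index=o.index)
    r = ref.series.data.dropna()
    head = r[r.index.year < switch_year]
    tail = corrected[corrected.index.year >= switch_year]
    merged = pd.concat([head, tail]).sort_index()
    if merged.index.has_duplicates:
        raise AssertionError("merged series has duplicate months")
    return MonthlySeries(
        ref.series.variable, ref.series.units, ref.series.band_id, merged
    )
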