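import dataclasses
import math

import numpy as np
import pandas as pd
import pytest

from pelagoshift import geo, series_trends, synthetic_data as sd
from pelagoshift.geo import KM_PER_DEG_LAT, GridSpec


def quiet(config):
    return dataclasses.replace(
        config,
        sst=dataclasses.replace(config.sst, noise_sigma=0.0),
        wind=dataclasses.replace(config.wind, noise_sigma=0.0),
        chl=dataclasses.replace(config.chl, log_noise_sigma=0.0),
    )


@pytest.fixture(scope="module")
def tiny_config():
    return sd.WorldConfig(grid=GridSpec(10.0, 32.0, -22.0, -10.0, 2.0), seed=5)


class TestConfigValidation:
    def test_bad_phi(self):
        with pytest.raises(ValueError, match="phi"):
            sd.WorldConfig(sst=sd.SSTConfig(ar1_phi=1.5))

    def test_bad_sigma(self):
        with pytest.raises(ValueError, match="sigma"):
            sd.WorldConfig(wind=sd.WindConfig(noise_sigma=-1.0))

    def test_bad_survey_year(self):
        with pytest.raises(ValueError, match="survey year"):
            sd.WorldConfig(surveys=sd.SurveyConfig(years=(1970,)))

    def test_infinite_drift(self):
        with pytest.raises(ValueError, match="drift"):
            sd.WorldConfig(
                species=(("x", sd.SpeciesConfig(drift_km_per_decade=np.inf)),)
            )


class TestDeterminism:
    def test_bit_identical_rebuild(self, tiny_config):
        w1 = sd.build_world(tiny_config, with_truth_trends=False)
        w2 = sd.build_world(tiny_config, with_truth_trends=False)
        np.testing.assert_array_equal(w1.sst.values, w2.sst.values)
        np.testing.assert_array_equal(w1.wind_u.values, w2.wind_u.values)
        np.testing.assert_array_equal(w1.chl_a.values, w2.chl_a.values)
        pd.testing.assert_frame_equal(w1.trawls, w2.trawls)
        pd.testing.assert_frame_equal(w1.acoustic_bins, w2.acoustic_bins)

    def test_seed_changes_noise(self, tiny_config):
        w1 = sd.build_world(tiny_config, with_truth_trends=False)
        w2 = sd.build_world(
            dataclasses.replace(tiny_config, seed=6), with_truth_trends=False
        )
        assert not np.array_equal(w1.sst.values, w2.sst.values)

    def test_adding_species_keeps_field_noise(self, tiny_config):
        w1 = sd.build_world(tiny_config, with_truth_trends=False)
        more = dataclasses.replace(
            tiny_config,
            species=tiny_config.species + (("extra", sd.SpeciesConfig()),),
        )
        w2 = sd.build_world(more, with_truth_trends=False)
        np.testing.assert_array_equal(w1.sst.values, w2.sst.values)
        np.testing.assert_array_equal(w1.wind_v.values, w2.wind_v.values)


class TestGenerateSST:
    def test_noise_free_formula_offshore(self, tiny_config):
        cfg = quiet(tiny_config)
        coast = sd.build_coast(cfg)
        fld = sd.generate_sst(cfg, coast)
        s = cfg.sst
        grid = cfg.grid
        # far-offshore cell (weak cooling), at the seasonal peak month
        i, j = 5, 0  # lat 21, lon -21: ~ >500 km offshore
        lat = grid.lat_centers[i]
        d = geo.distance_to_coast_field(grid, coast)[i, j]
        k = list(fld.time).index(pd.Period(f"1990-{s.peak_month:02d}", "M"))
        t_years = (1990 - s.start_year) + (s.peak_month - 0.5) / 12.0
        expected = (
            s.mean_at_12n
            - s.gradient_per_deg * (lat - 12.0)
            + s.seasonal_amplitude
            + s.trend_per_decade / 10.0 * t_years
            - s.cooling_max
            * math.exp(-d / s.cooling_efold_km)
            * 0.5
            * (1 + math.cos(2 * math.pi * (s.peak_month - s.cooling_peak_month) / 12))
        )
        assert fld.values[k, i, j] == pytest.approx(expected, abs=1e-12)

    def test_coastal_cell_colder(self, tiny_config):
        cfg = quiet(tiny_config)
        coast = sd.build_coast(cfg)
        fld = sd.generate_sst(cfg, coast)
        d = geo.distance_to_coast_field(cfg.grid, coast)
        i = 5
        row_d = d[i]
        ocean = np.isfinite(row_d)
        near = np.nanargmin(row_d)
        far = np.nanargmax(np.where(ocean, row_d, -np.inf))
        k = list(fld.time).index(pd.Period(f"1990-{cfg.sst.cooling_peak_month:02d}", "M"))
        s = cfg.sst
        expected_diff = s.cooling_max * (
            math.exp(-row_d[near] / s.cooling_efold_km)
            - math.exp(-row_d[far] / s.cooling_efold_km)
        )
        assert fld.values[k, i, far] - fld.values[k, i, near] == pytest.approx(
            expected_diff, abs=1e-12
        )

    def test_band_trend_recovered_exactly_noise_free(self, tiny_config):
        cfg = quiet(dataclasses.replace(
            tiny_config, sst=dataclasses.replace(tiny_config.sst, trend_per_decade=0.3)
        ))
        coast = sd.build_coast(cfg)
        fld = sd.generate_sst(cfg, coast)
        mask = geo.coastal_mask(cfg.grid, coast, 150.0)
        s = geo.area_series(fld, mask, geo.AreaBand(4, 16.0, 21.0))
        yearly = series_trends.annual_mean(
            series_trends.MonthlySeries("sst", "degC", 4, s)
        ).dropna()
        res = series_trends.linear_trend(yearly.index.to_numpy(), yearly.to_numpy())
        assert res.slope_per_decade == pytest.approx(0.3, abs=1e-10)

    def test_step_change(self, tiny_config):
        cfg = quiet(dataclasses.replace(
            tiny_config,
            sst=dataclasses.replace(
                tiny_config.sst, step_year=1995, step_degc=0.8, trend_per_decade=0.0
            ),
        ))
        coast = sd.build_coast(cfg)
        fld = sd.generate_sst(cfg, coast)
        jan94 = list(fld.time).index(pd.Period("1994-01", "M"))
        jan96 = list(fld.time).index(pd.Period("1996-01", "M"))
        diff = fld.values[jan96] - fld.values[jan94]
        np.testing.assert_allclose(diff[np.isfinite(diff)], 0.8, atol=1e-12)

    def test_ar1_long_run_mean(self):
        rng = np.random.default_rng(10)
        phi, sigma, n = 0.6, 0.3, 480
        x = sd._ar1_noise(rng, phi, sigma, (n, 50))
        # AR(1) standard error oracle: var(mean) ~ sigma^2/n * (1+phi)/(1-phi)
        n_eff = n * (1 - phi) / (1 + phi)
        se = sigma / math.sqrt(n_eff)
        means = x.mean(axis=0)
        assert (np.abs(means) < 3 * se).mean() > 0.95

    def test_ar1_marginal_variance(self):
        rng = np.random.default_rng(11)
        x = sd._ar1_noise(rng, 0.6, 0.3, (4000, 20))
        assert x.std() == pytest.approx(0.3, rel=0.05)


class TestGenerateWind:
    def test_noise_free_speed_at_coast(self, tiny_config):
        cfg = quiet(tiny_config)
        coast = sd.build_coast(cfg)
        u, v = sd.generate_wind(cfg, coast)
        w = cfg.wind
        time = u.time
        months = np.asarray(time.month)
        tfrac = np.asarray(
            (time.year - w.start_year) + (time.month - 0.5) / 12.0
        )
        expected = (
            w.mean_speed
            + w.seasonal_amplitude * np.cos(2 * np.pi * (months - w.peak_month) / 12)
            + w.trend_per_decade / 10.0 * tfrac
        )
        speed = np.hypot(u.values, v.values)
        np.testing.assert_allclose(speed[:, 3, 2], expected, atol=1e-9)

    def test_equatorward_direction(self, tiny_config):
        cfg = quiet(tiny_config)
        coast = sd.build_coast(cfg)
        u, v = sd.generate_wind(cfg, coast)
        # alongshore equatorward: v strictly negative for a poleward tangent
        assert (v.values < 0).all()

    def test_trend_recovery_noise_free(self, tiny_config):
        cfg = quiet(tiny_config)
        coast = sd.build_coast(cfg)
        u, v = sd.generate_wind(cfg, coast)
        speed = geo.GridField("ws", "m s-1", u.grid, u.time,
                              np.hypot(u.values, v.values))
        mask = geo.coastal_mask(cfg.grid, coast, 150.0)
        s = geo.area_series(speed, mask, geo.AreaBand(4, 16.0, 21.0))
        yearly = series_trends.annual_mean(
            series_trends.MonthlySeries("ws", "", 4, s)
        ).dropna()
        res = series_trends.linear_trend(yearly.index.to_numpy(), yearly.to_numpy())
        assert res.slope_per_decade == pytest.approx(
            cfg.wind.trend_per_decade, abs=1e-10
        )


class TestGenerateChl:
    def test_equal_bias_no_noise_sensors_identical_on_overlap(self, tiny_config):
        cfg = quiet(dataclasses.replace(
            tiny_config, chl=dataclasses.replace(tiny_config.chl, bias_a=1.0, bias_b=1.0)
        ))
        coast = sd.build_coast(cfg)
        proxy = sd.upwelling_proxy_field(cfg, coast)
        a, b = sd.generate_chl(cfg, proxy)
        years = np.asarray(a.time.year)
        overlap = (years >= 2003) & (years <= 2010)
        np.testing.assert_array_equal(a.values[overlap], b.values[overlap])

    def test_bias_ratio_recovered_from_log_difference(self, tiny_config):
        cfg = quiet(tiny_config)
        coast = sd.build_coast(cfg)
        proxy = sd.upwelling_proxy_field(cfg, coast)
        a, b = sd.generate_chl(cfg, proxy)
        years = np.asarray(a.time.year)
        overlap = (years >= 2003) & (years <= 2010)
        va, vb = a.values[overlap], b.values[overlap]
        ok = np.isfinite(va) & np.isfinite(vb)
        log_diff = np.log10(vb[ok]) - np.log10(va[ok])
        ratio = cfg.chl.bias_b / cfg.chl.bias_a
        assert log_diff.mean() == pytest.approx(np.log10(ratio), abs=1e-12)

    def test_positive_everywhere(self, tiny_config):
        coast = sd.build_coast(tiny_config)
        proxy = sd.upwelling_proxy_field(tiny_config, coast)
        rng = np.random.default_rng(0)
        a, b = sd.generate_chl(tiny_config, proxy, rng=rng)
        assert np.all(a.values[np.isfinite(a.values)] > 0)
        assert np.all(b.values[np.isfinite(b.values)] > 0)

    def test_sensor_spans(self, tiny_config):
        coast = sd.build_coast(tiny_config)
        proxy = sd.upwelling_proxy_field(tiny_config, coast)
        a, b = sd.generate_chl(quiet(tiny_config), proxy)
        years = np.asarray(a.time.year)
        assert np.isnan(a.values[years > 2010]).all()
        assert np.isnan(b.values[years < 2003]).all()
        assert np.isfinite(b.values[years >= 2003]).any()
        assert np.isfinite(a.values[years <= 2010]).any()


class TestSurveys:
    def _step_config(self, tiny_config, drift=180.0, detection=1.0):
        sp = sd.SpeciesConfig(
            initial_limit=19.0,
            drift_km_per_decade=drift,
            occupancy_steepness=0.0,
            detection_probability=detection,
        )
        return dataclasses.replace(tiny_config, species=(("sp", sp),))

    def test_step_occupancy_presence_iff_south_of_limit(self, tiny_config):
        cfg = self._step_config(tiny_config)
        coast = sd.build_coast(cfg)
        rng = np.random.default_rng(0)
        trawls, _, _ = sd.generate_surveys(cfg, coast, rng)
        first = cfg.surveys.years[0]
        for year, grp in trawls.groupby("year"):
            limit = sd.true_limit(cfg.species[0][1], year, first)
            present = grp[grp["sp"] > 0]
            absent = grp[grp["sp"] == 0]
            assert (present["lat"] < limit).all()
            assert (absent["lat"] >= limit).all()

    def test_observed_limit_is_truth_rounded_to_transect(self, tiny_config):
        from pelagoshift import survey_shift as ss

        cfg = self._step_config(tiny_config)
        coast = sd.build_coast(cfg)
        rng = np.random.default_rng(0)
        trawls, _, meta = sd.generate_surveys(cfg, coast, rng)
        sv = cfg.surveys
        first = sv.years[0]
        for year in sv.years:
            res = ss.northern_limit(trawls, "sp", year, meta)
            limit = sd.true_limit(cfg.species[0][1], year, first)
            transects = sd._transect_lats(sv, year)
            expected = transects[transects < limit].max()
            assert res is not None and res[0] == pytest.approx(expected)

    def test_meta_flags(self, tiny_config):
        coast = sd.build_coast(tiny_config)
        _, bins, meta = sd.generate_surveys(
            tiny_config, coast, np.random.default_rng(1)
        )
        assert not meta.loc[2011, "has_biomass"]
        assert meta.loc[2005, "coverage_north_limit"] == 26.3
        assert 2011 not in set(bins["year"])

    def test_coverage_south_of_transects_errors(self, tiny_config):
        bad = dataclasses.replace(
            tiny_config,
            surveys=dataclasses.replace(
                tiny_config.surveys,
                coverage_overrides=((2005, 11.0),),
                southern_limit=12.0,
            ),
        )
        coast = sd.build_coast(bad)
        with pytest.raises(ValueError, match="south of all transects"):
            sd.generate_surveys(bad, coast, np.random.default_rng(0))

    def test_truth_fraction_monotone_for_drifting_species(self, tiny_config):
        w = sd.build_world(tiny_config, with_truth_trends=False)
        frac = w.truth.fraction_north["drifter"]
        years = sorted(y for y in frac if y != 2005)  # 2005 has short coverage
        vals = [frac[y] for y in years]
        assert vals == sorted(vals)
        assert vals[-1] > vals[0]


class TestTruthRecord:
    def test_realized_trends_match_configured(self, tiny_config):
        w = sd.build_world(tiny_config)
        for band_id, val in w.truth.band_trends["sst"].items():
            assert val == pytest.approx(tiny_config.sst.trend_per_decade, abs=1e-9)
        for band_id, val in w.truth.band_trends["wind_speed"].items():
            assert val == pytest.approx(tiny_config.wind.trend_per_decade, abs=1e-9)

    def test_species_truth(self, tiny_config):
        w = sd.build_world(tiny_config, with_truth_trends=False)
        assert w.truth.species_drift["drifter"] == 180.0
        lims = w.truth.species_limits["drifter"]
        drift_deg = 180.0 / KM_PER_DEG_LAT / 10.0
        assert lims[2015] - lims[1995] == pytest.approx(20 * drift_deg)


def test_sst_band_trend_estimates_center_on_truth():
    """200 replicate worlds: band-trend estimator bias < 0.02 degC/decade."""
    grid = GridSpec(14.0, 22.0, -20.0, -14.0, 1.0)
    base = sd.WorldConfig(grid=grid)
    coast = sd.build_coast(base)
    distances = geo.distance_to_coast_field(grid, coast)
    mask = geo.coastal_mask(grid, coast, 100.0, distances=distances)
    band = geo.AreaBand(4, 16.0, 21.0)
    est = []
    for seed in range(200):
        rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
        fld = sd.generate_sst(base, coast, rng=rng, distances=distances)
        s = geo.area_series(fld, mask, band)
        yearly = series_trends.annual_mean(
            series_trends.MonthlySeries("sst", "degC", 4, s)
        ).dropna()
        est.append(
            series_trends.linear_trend(
                yearly.index.to_numpy(), yearly.to_numpy()
            ).slope_per_decade
        )
    bias = np.mean(est) - base.sst.trend_per_decade
    assert abs(bias) < 0.02
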