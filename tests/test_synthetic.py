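"""Synthetic mountain-survey generator: determinism, structure, recovery."""

import numpy as np
import pytest
import yaml

from socmap.geodata import LandUse, Raster
from socmap.synthetic import (
    SurveyConfig,
    assign_landuse,
    generate_dem,
    generate_ndvi,
    generate_park,
    recover_variogram,
    sample_survey,
    simulate_soc_field,
    write_fixture_bundle,
)
from socmap.variogram import VariogramModel, empirical_semivariogram


class TestDEM:
    def test_same_seed_identical(self):
        a = generate_dem(SurveyConfig(seed=3))
        b = generate_dem(SurveyConfig(seed=3))
        np.testing.assert_array_equal(a.values, b.values)

    def test_centre_near_configured_maximum(self, default_cfg, default_park):
        n = default_park.dem.n_rows
        centre = default_park.dem.values[n // 2, n // 2]
        amax = default_cfg.altitude_range[1]
        assert centre == pytest.approx(amax, abs=2 * default_cfg.dem_noise_amp)

    def test_ring_averaged_altitude_declines_with_radius(self, default_park, default_cfg):
        dem = default_park.dem
        X, Y = dem.cell_centers()
        c = default_cfg.extent_m / 2
        r = np.hypot(X - c, Y - c)
        edges = np.linspace(0, c, 8)
        means = [dem.values[(r >= lo) & (r < hi)].mean()
                 for lo, hi in zip(edges[:-1], edges[1:])]
        assert np.all(np.diff(means) < 0)


class TestLanduse:
    def make_dem(self, alts):
        return Raster(np.array(alts, dtype=float), 0.0, 0.0, 200.0)

    def test_altitude_band_classes(self):
        cfg = SurveyConfig(seed=0)
        dem = self.make_dem([[4100.0, 2300.0, 3500.0]])
        lu = assign_landuse(dem, cfg)
        assert lu.values[0, 0] == LandUse.GRASSLAND.code
        assert lu.values[0, 1] == LandUse.AGRICULTURE.code
        assert lu.values[0, 2] == LandUse.FOREST.code

    def test_band_edge_belongs_to_lower_band(self):
        """3000.0 m sits in the 2500-3000 band (mixed), not pure forest."""
        cfg = SurveyConfig(seed=0, p_forest_mixed=0.0)  # mixed band -> agriculture
        dem = self.make_dem([[3000.0, 3000.0001]])
        lu = assign_landuse(dem, cfg)
        assert lu.values[0, 0] == LandUse.AGRICULTURE.code
        assert lu.values[0, 1] == LandUse.FOREST.code

    def test_altitude_outside_bands_rejected(self):
        cfg = SurveyConfig(seed=0)
        with pytest.raises(ValueError, match="outside"):
            assign_landuse(self.make_dem([[1000.0]]), cfg)

    def test_mixed_band_marginal_probability(self):
        cfg = SurveyConfig(seed=1, p_forest_mixed=0.3)
        dem = Raster(np.full((60, 60), 2750.0), 0.0, 0.0, 200.0)
        lu = assign_landuse(dem, cfg)
        frac = np.mean(lu.values == LandUse.FOREST.code)
        assert frac == pytest.approx(0.3, abs=0.02)


class TestSocField:
    def forest_only_cfg(self, **kw):
        cfg = SurveyConfig(seed=2, **kw)
        lu = Raster(np.full((100, 100), float(LandUse.FOREST.code)), 0.0, 0.0,
                    cfg.cell_size)
        return cfg, lu

    def test_nugget_only_field_is_uncorrelated(self):
        cfg, lu = self.forest_only_cfg(
            variogram=VariogramModel("exponential", 0.5, 1e-12, 3000.0))
        field = np.log(simulate_soc_field(lu, cfg).values)
        r = np.corrcoef(field[:, :-1].ravel(), field[:, 1:].ravel())[0, 1]
        assert abs(r) < 0.05

    def test_realization_variogram_matches_model(self):
        """Empirical semivariogram of one field vs the input curve, <=15%
        relative at lags within the range."""
        cfg, lu = self.forest_only_cfg()
        field = simulate_soc_field(lu, cfg)
        vm = cfg.variogram
        rng = np.random.default_rng(0)
        X, Y = field.cell_centers()
        pick = rng.choice(field.values.size, 1500, replace=False)
        coords = np.column_stack([X.ravel()[pick], Y.ravel()[pick]])
        z = np.log(field.values.ravel()[pick])
        ev = empirical_semivariogram(coords, z, max_lag=vm.range_param, n_lags=6)
        lags, gam, _ = ev.nonempty()
        np.testing.assert_allclose(gam, vm(lags), rtol=0.15)

    def test_strictly_positive(self, default_park):
        vals = default_park.soc_field.values
        assert np.all(vals[~np.isnan(vals)] > 0)

    def test_stratum_means_within_two_standard_errors(self, default_park, default_cfg):
        lu = default_park.landuse.values
        soc = default_park.soc_field.values
        for land_use, sp in default_cfg.strata.items():
            v = soc[lu == land_use.code]
            # spatially correlated cells: effective n ~ one per range-sized patch
            n_eff = max(v.size * (default_cfg.cell_size /
                                  default_cfg.variogram.range_param) ** 2, 4.0)
            se = v.std() / np.sqrt(n_eff)
            assert abs(v.mean() - sp.mean_soc) <= 2 * se

    def test_sample_sd_matches_generative_model(self, default_sites, default_cfg):
        """Within-stratum dispersion follows the field's lognormal, whose
        log-variance is the variogram sill (not the tabulated survey SDs;
        both cannot hold at once -- see the methods note)."""
        sill = default_cfg.variogram.sill
        for land_use, sp in default_cfg.strata.items():
            v = np.array([s.soc_a for s in default_sites if s.land_use == land_use])
            if len(v) < 100:
                continue
            implied_cv = np.sqrt(np.exp(sill) - 1.0)
            # log-scale SD is the robust check for a heavy-tailed lognormal
            assert np.std(np.log(v)) == pytest.approx(np.sqrt(sill), rel=0.35)
            assert implied_cv > 1.0  # regime: dispersion dominated by the field


class TestSurvey:
    def test_default_survey_size_and_invariants(self, default_sites):
        assert len(default_sites) == 440
        ids = {s.site_id for s in default_sites}
        assert len(ids) == 440

    def test_agriculture_has_no_o_horizon(self, default_sites):
        ag = [s for s in default_sites if s.land_use == LandUse.AGRICULTURE]
        assert ag and all(s.o_thickness == 0 and s.soc_o is None for s in ag)
        forest = [s for s in default_sites if s.land_use == LandUse.FOREST]
        assert any(s.o_thickness > 0 for s in forest)

    def test_seed_determinism(self, default_park, default_cfg, default_sites):
        again = sample_survey(default_park, default_cfg)
        assert again == default_sites
        cfg2 = SurveyConfig(seed=99)
        other = sample_survey(generate_park(cfg2), cfg2)
        assert [s.x for s in other] != [s.x for s in default_sites]

    def test_stratum_counts_roughly_proportional_to_area(self, default_park,
                                                         default_sites):
        lu = default_park.landuse.values
        for land_use in LandUse:
            area_frac = np.mean(lu == land_use.code)
            count_frac = np.mean([s.land_use == land_use for s in default_sites])
            assert count_frac == pytest.approx(area_frac, abs=0.06)


class TestNdvi:
    def test_monotone_link_without_noise(self):
        cfg = SurveyConfig(seed=5, ndvi_noise_sd=0.0)
        lu = Raster(np.full((50, 50), float(LandUse.FOREST.code)), 0.0, 0.0,
                    cfg.cell_size)
        soc = simulate_soc_field(lu, cfg)
        ndvi = generate_ndvi(soc, cfg)
        inside = (ndvi.values > -1) & (ndvi.values < 1)
        from scipy.stats import spearmanr

        rho, _ = spearmanr(soc.values[inside].ravel(), ndvi.values[inside].ravel())
        assert rho == pytest.approx(1.0, abs=1e-12)

    def test_bounded(self, default_park):
        v = default_park.ndvi.values
        assert np.nanmin(v) >= -1.0 and np.nanmax(v) <= 1.0

    def test_default_correlation_with_soc(self, default_park):
        ok = ~np.isnan(default_park.ndvi.values)
        r = np.corrcoef(default_park.ndvi.values[ok].ravel(),
                        default_park.soc_field.values[ok].ravel())[0, 1]
        assert 0.4 <= r <= 0.9


class TestRecovery:
    def test_variogram_parameters_recovered_in_8_of_10_seeds(self):
        hits = 0
        for seed in range(10):
            cfg = SurveyConfig(seed=seed)
            sites = sample_survey(generate_park(cfg), cfg)
            vm = recover_variogram(sites, cfg)
            truth = cfg.variogram
            if (abs(vm.nugget - truth.nugget) <= 0.3 * truth.nugget
                    and abs(vm.sill - truth.sill) <= 0.3 * truth.sill):
                hits += 1
        assert hits >= 8


class TestFixtureBundle:
    def test_bundle_written_and_truth_echoed(self, tmp_path):
        cfg = SurveyConfig(seed=4, n_sites=60)
        manifest = write_fixture_bundle(cfg, tmp_path)
        for key in ("samples", "dem", "landuse", "landuse_polygons",
                    "ndvi", "nir", "red", "truth"):
            assert key in manifest
        truth = yaml.safe_load(open(tmp_path / "truth.yaml"))
        assert truth["variogram"]["nugget"] == pytest.approx(0.529)
        assert truth["variogram"]["sill"] == pytest.approx(2.226)
        import pandas as pd

        assert len(pd.read_csv(tmp_path / "samples.csv")) == 60
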