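"""Synthetic landscape generator: determinism, autocorrelation, arm coupling."""

import numpy as np
import pytest

import pacteval as pe
from pacteval.landscape import hazard_probability, rasterize_polygon


def lag1_correlation(field: np.ndarray) -> float:
    """Pearson correlation between horizontally adjacent pixels."""
    a, b = field[:, :-1].ravel(), field[:, 1:].ravel()
    return float(np.corrcoef(a, b)[0, 1])


class TestGenerateCovariates:
    def test_deterministic_under_fixed_seed(self):
        grid = pe.GridSpec(100, 100)
        s1 = pe.generate_covariates(grid, seed=7)
        s2 = pe.generate_covariates(grid, seed=7)
        for name in ("elevation", "slope", "accessibility", "country", "ecoregion"):
            np.testing.assert_array_equal(getattr(s1, name), getattr(s2, name))

    def test_different_seeds_differ(self):
        grid = pe.GridSpec(50, 50)
        s1 = pe.generate_covariates(grid, seed=1)
        s2 = pe.generate_covariates(grid, seed=2)
        assert not np.array_equal(s1.elevation, s2.elevation)

    def test_large_smoothness_flattens_fields(self):
        grid = pe.GridSpec(50, 50)
        rough = pe.generate_covariates(grid, smoothness=100.0, seed=3)
        flat = pe.generate_covariates(grid, smoothness=1e6, seed=3)
        assert flat.elevation.std() < 0.05 * rough.elevation.std()
        assert flat.slope.max() < 0.05 * max(rough.slope.max(), 1e-12) + 1e-9

    def test_spatial_autocorrelation(self):
        stack = pe.generate_covariates(pe.GridSpec(200, 200, pixel_size=30.0), seed=1)
        assert lag1_correlation(stack.elevation) > 0.5

    def test_invalid_grid_rejected_naming_field(self):
        with pytest.raises(ValueError, match="n_rows"):
            pe.GridSpec(0, 10)
        with pytest.raises(ValueError, match="pixel_size"):
            pe.GridSpec(10, 10, pixel_size=-1)

    def test_nonpositive_smoothness_rejected(self):
        with pytest.raises(ValueError, match="smoothness"):
            pe.generate_covariates(pe.GridSpec(10, 10), smoothness=0.0)

    def test_categorical_regions_present(self):
        stack = pe.generate_covariates(pe.GridSpec(60, 60), seed=4, n_ecoregions=3)
        assert len(np.unique(stack.ecoregion)) >= 1
        assert stack.slope.min() >= 0 and stack.slope.max() <= 90

    def test_pixel_area_unit(self):
        assert pe.GridSpec(1, 1, pixel_size=30.0).pixel_area == pytest.approx(0.09)


@pytest.fixture(scope="module")
def covariate_stack():
    return pe.generate_covariates(pe.GridSpec(120, 120, pixel_size=100.0), seed=5)


class TestSimulateLandcover:
    def _polygon(self, stack):
        from shapely.geometry import box

        return box(2000, 2000, 6000, 6000)  # 40x40 pixels at 100 m

    def test_null_multiplier_gives_identical_arms(self, covariate_stack):
        hz = pe.HazardModel(treatment_multiplier=1.0)
        scen = pe.simulate_landcover(
            covariate_stack, hz, (2000, 2015), 2005, self._polygon(covariate_stack), seed=3
        )
        np.testing.assert_array_equal(scen.factual.landcover, scen.counterfactual.landcover)
        assert (scen.truth_table["avoided_ha"] == 0).all()
        assert scen.true_avoided_ha == 0.0

    def test_zero_hazard_freezes_landscape(self, covariate_stack):
        hz = pe.HazardModel(intercept=-60.0, spatial_noise_sd=0.0)
        scen = pe.simulate_landcover(
            covariate_stack, hz, (2000, 2010), 2005, self._polygon(covariate_stack), seed=3
        )
        und = scen.truth_table["factual_undisturbed_ha"]
        assert und.nunique() == 1  # no conversions at all

    def test_t0_outside_years_rejected(self, covariate_stack):
        with pytest.raises(ValueError, match="t0"):
            pe.simulate_landcover(
                covariate_stack, pe.HazardModel(), (2000, 2010), 2010,
                self._polygon(covariate_stack), seed=1,
            )

    def test_arms_equal_outside_project_and_before_t0(self, covariate_stack):
        scen = pe.simulate_landcover(
            covariate_stack, pe.HazardModel(), (2000, 2015), 2005,
            self._polygon(covariate_stack), seed=9,
        )
        mask = rasterize_polygon(scen.project_polygon, covariate_stack.grid)
        f, c = scen.factual.landcover, scen.counterfactual.landcover
        np.testing.assert_array_equal(f[:, ~mask], c[:, ~mask])
        i0 = scen.factual.year_index(2005)
        np.testing.assert_array_equal(f[: i0 + 1], c[: i0 + 1])

    def test_undisturbed_never_recreated(self, covariate_stack):
        scen = pe.simulate_landcover(
            covariate_stack, pe.HazardModel(), (2000, 2012), 2005,
            self._polygon(covariate_stack), seed=2,
        )
        lc = scen.factual.landcover
        was_lost = np.zeros(lc.shape[1:], dtype=bool)
        for i in range(1, lc.shape[0]):
            was_lost |= (lc[i - 1] == pe.LandCover.UNDISTURBED) & (lc[i] != pe.LandCover.UNDISTURBED)
            assert not np.any(was_lost & (lc[i] == pe.LandCover.UNDISTURBED))

    def test_avoided_matches_analytic_expectation(self):
        """Known-effect truth agrees with the closed-form per-pixel survival
        expectation (1 - m*h)^t vs (1 - h)^t averaged over pixel hazards."""
        stack = pe.generate_covariates(pe.GridSpec(150, 150, pixel_size=100.0), seed=21)
        from shapely.geometry import box

        polygon = box(2000, 2000, 12_000, 12_000)  # 10^4 pixels
        hz = pe.HazardModel(treatment_multiplier=0.5)
        t0, end = 2001, 2011
        scen = pe.simulate_landcover(stack, hz, (2000, end), t0, polygon, seed=77, noise_seed=77)
        p = hazard_probability(stack, hz, noise_seed=77)
        mask = rasterize_polygon(polygon, stack.grid)
        i0 = scen.factual.year_index(t0)
        und0 = scen.factual.landcover[i0] == pe.LandCover.UNDISTURBED
        h = p[mask & und0]
        t = end - t0
        per_pixel = (1 - hz.treatment_multiplier * h) ** t - (1 - h) ** t
        expected = per_pixel.sum() * stack.grid.pixel_area
        mc_sd = np.sqrt((per_pixel * (1 - per_pixel)).sum()) * stack.grid.pixel_area
        assert abs(scen.true_avoided_ha - expected) < 5 * mc_sd + stack.grid.pixel_area

    @pytest.mark.parametrize("seed", range(20))
    def test_treatment_monotonicity(self, covariate_stack, seed):
        """Lowering the multiplier never decreases avoided deforestation
        (exact per seed thanks to common random numbers)."""
        poly = self._polygon(covariate_stack)
        avoided = []
        for m in (0.8, 0.4):
            hz = pe.HazardModel(treatment_multiplier=m)
            scen = pe.simulate_landcover(
                covariate_stack, hz, (2003, 2013), 2005, poly, seed=seed, noise_seed=seed
            )
            avoided.append(scen.true_avoided_ha)
        assert avoided[1] >= avoided[0]

    def test_scenario_determinism(self):
        a = pe.make_scenario(grid=pe.GridSpec(80, 80, pixel_size=100.0),
                             project_shape=(20, 20), seed=13)
        b = pe.make_scenario(grid=pe.GridSpec(80, 80, pixel_size=100.0),
                             project_shape=(20, 20), seed=13)
        np.testing.assert_array_equal(a.factual.landcover, b.factual.landcover)
        assert a.project_polygon.equals(b.project_polygon)
        assert a.true_avoided_ha == b.true_avoided_ha


def window_mean_min_oracle(p: np.ndarray, h: int, w: int) -> float:
    """Brute-force minimum window mean via an integral image."""
    ii = np.zeros((p.shape[0] + 1, p.shape[1] + 1))
    ii[1:, 1:] = np.cumsum(np.cumsum(p, axis=0), axis=1)
    best = np.inf
    for r0 in range(p.shape[0] - h + 1):
        for c0 in range(p.shape[1] - w + 1):
            s = ii[r0 + h, c0 + w] - ii[r0, c0 + w] - ii[r0 + h, c0] + ii[r0, c0]
            best = min(best, s / (h * w))
    return best


class TestPlacePolygons:
    def test_symmetric_bias_orders_mean_hazard(self):
        stack = pe.generate_covariates(pe.GridSpec(100, 100, pixel_size=100.0), seed=6)
        hz = pe.HazardModel()
        proj, ref = pe.place_polygons(stack, hz, siting_bias=0.5, seed=6,
                                      project_shape=(20, 20))
        p = hazard_probability(stack, hz, noise_seed=6)
        mp = rasterize_polygon(proj, stack.grid)
        mr = rasterize_polygon(ref, stack.grid)
        assert p[mp].mean() <= p[mr].mean()
        assert not proj.intersects(ref)

    def test_zero_bias_hits_minimum_hazard_neighbourhood(self):
        stack = pe.generate_covariates(pe.GridSpec(80, 80, pixel_size=100.0), seed=8)
        hz = pe.HazardModel(spatial_noise_sd=0.0)
        proj, _ = pe.place_polygons(stack, hz, siting_bias=0.0, seed=8, noise_seed=8,
                                    project_shape=(16, 16))
        p = hazard_probability(stack, hz, noise_seed=8)
        mask = rasterize_polygon(proj, stack.grid)
        assert p[mask].mean() == pytest.approx(window_mean_min_oracle(p, 16, 16), rel=1e-10)

    def test_grid_too_small_rejected(self):
        stack = pe.generate_covariates(pe.GridSpec(10, 10), seed=1)
        with pytest.raises(ValueError, match="too small"):
            pe.place_polygons(stack, pe.HazardModel(), project_shape=(10, 10),
                              reference_shape=(10, 10), seed=1)

    def test_invalid_bias_rejected(self):
        stack = pe.generate_covariates(pe.GridSpec(20, 20), seed=1)
        with pytest.raises(ValueError, match="siting_bias"):
            pe.place_polygons(stack, pe.HazardModel(), siting_bias=1.5, seed=1)

    def test_reference_more_accessible_than_project(self):
        """Biased siting reproduces the field pattern: reference areas sit in
        more accessible (shorter travel time) terrain, i.e. negative
        accessibility SMD of reference vs project, in nearly every run."""
        signs = []
        for seed in range(20):
            stack = pe.generate_covariates(
                pe.GridSpec(150, 150, pixel_size=100.0), smoothness=1000.0, seed=seed
            )
            hz = pe.HazardModel()
            proj, ref = pe.place_polygons(stack, hz, siting_bias=0.25, seed=seed,
                                          project_shape=(30, 30))
            mp = rasterize_polygon(proj, stack.grid)
            mr = rasterize_polygon(ref, stack.grid)
            val = pe.smd(stack.accessibility[mr], stack.accessibility[mp])
            signs.append(val < 0)
        assert sum(signs) >= 18
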