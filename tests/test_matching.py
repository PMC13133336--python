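"""PACT matching: sampling lattice, neighbourhood cover, pool filters,
greedy Mahalanobis pairing (against a brute-force oracle) and the SMD gate."""

import numpy as np
import pandas as pd
import pytest
import shapely
from shapely.geometry import Polygon, box

import pacteval as pe
from pacteval.grids import LandCover
from pacteval.matching import (
    CATEGORICAL_COVARIATES,
    CONTINUOUS_COVARIATES,
    AllIterationsRejectedError,
    EmptyPoolError,
    auto_density,
    candidate_pool,
    sample_units,
    unit_table,
)

from conftest import random_unit_frame


class TestSampleUnits:
    def test_density_times_area(self):
        # 100 ha rectangle at 0.25 pt/ha -> 25 points on a uniform lattice
        grid = pe.GridSpec(60, 60, pixel_size=30.0)
        poly = box(120, 120, 1120, 1120)  # 1000 m x 1000 m = 100 ha
        rows, cols = sample_units(poly, grid, density=0.25)
        assert len(rows) == 25

    def test_auto_density_rule(self):
        assert auto_density(100.0) == 0.25
        assert auto_density(249_999.0) == 0.25
        assert auto_density(300_000.0) == 0.05

    def test_irregular_polygon_centres_inside(self):
        """Every returned pixel centre passes an independent point-in-triangle
        check (sign of cross products, no shapely involved)."""
        grid = pe.GridSpec(80, 80, pixel_size=30.0)
        tri = [(100.0, 100.0), (2300.0, 300.0), (700.0, 2300.0)]
        poly = Polygon(tri)
        rows, cols = sample_units(poly, grid, density=0.25)
        x, y = grid.pixel_centers(rows, cols)

        def cross(o, a, px, py):
            return (a[0] - o[0]) * (py - o[1]) - (a[1] - o[1]) * (px - o[0])

        for px, py in zip(x, y):
            s = [cross(tri[i], tri[(i + 1) % 3], px, py) for i in range(3)]
            assert all(v >= 0 for v in s) or all(v <= 0 for v in s)

    def test_no_intersection_rejected(self):
        grid = pe.GridSpec(10, 10, pixel_size=30.0)
        with pytest.raises(ValueError, match="polygon"):
            sample_units(box(10_000, 10_000, 11_000, 11_000), grid, density=0.25)


class TestProportionalCover:
    def test_uniform_rasters(self):
        layer = np.full((40, 40), LandCover.UNDISTURBED, dtype=np.uint8)
        cover = pe.proportional_cover(layer, LandCover.UNDISTURBED, pixel_size=30.0)
        np.testing.assert_allclose(cover, 1.0, atol=1e-9)
        cover0 = pe.proportional_cover(layer, LandCover.DEFORESTED, pixel_size=30.0)
        np.testing.assert_allclose(cover0, 0.0, atol=1e-9)

    def test_half_plane_matches_disc_enumeration(self):
        """Interior pixel on a half-plane boundary: fraction equals an exact
        enumeration of disc offsets (about one half)."""
        n, px, radius = 101, 30.0, 1000.0
        layer = np.full((n, n), LandCover.DEFORESTED, dtype=np.uint8)
        layer[:, : n // 2 + 1] = LandCover.UNDISTURBED  # cols 0..50 forest
        cover = pe.proportional_cover(layer, LandCover.UNDISTURBED, px, radius)
        r_px = int(radius // px)
        offs = [
            (dr, dc)
            for dr in range(-r_px, r_px + 1)
            for dc in range(-r_px, r_px + 1)
            if (dr * dr + dc * dc) * px * px <= radius * radius
        ]
        centre = n // 2
        expected = sum(1 for _, dc in offs if centre + dc <= n // 2) / len(offs)
        assert cover[centre, centre] == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(0.5, abs=0.05)  # one row quantisation

    def test_edge_truncation_denominator(self):
        layer = np.full((30, 30), LandCover.UNDISTURBED, dtype=np.uint8)
        cover = pe.proportional_cover(layer, LandCover.UNDISTURBED, 30.0, 300.0)
        assert cover[0, 0] == pytest.approx(1.0, abs=1e-9)  # truncated but still all-forest

    def test_unknown_class_rejected(self):
        layer = np.ones((5, 5), dtype=np.uint8)
        with pytest.raises(ValueError, match="class"):
            pe.proportional_cover(layer, 99, 30.0)

    def test_radius_below_pixel_rejected(self):
        layer = np.ones((5, 5), dtype=np.uint8)
        with pytest.raises(ValueError, match="radius"):
            pe.proportional_cover(layer, LandCover.UNDISTURBED, 30.0, radius=10.0)


def _flat_stack(n=120, pixel=100.0, elev=500.0):
    """A perfectly uniform landscape with a static all-undisturbed series."""
    grid = pe.GridSpec(n, n, pixel_size=pixel)
    shape = grid.shape
    years = np.arange(1999, 2013)
    lc = np.full((len(years), *shape), LandCover.UNDISTURBED, dtype=np.uint8)
    return pe.LandscapeStack(
        grid=grid,
        elevation=np.full(shape, elev),
        slope=np.full(shape, 5.0),
        accessibility=np.full(shape, 60.0),
        country=np.zeros(shape, dtype=np.int16),
        ecoregion=np.zeros(shape, dtype=np.int16),
        landcover=lc,
        years=years,
    )


class TestCandidatePool:
    def test_annulus_matches_bruteforce_filter(self):
        """Uniform landscape, no other projects: the pool is exactly the set
        of pixels between 5 km and 2000 km of the project polygon, checked by
        per-pixel distance enumeration."""
        stack = _flat_stack(n=150)
        poly = box(6000, 6000, 8000, 8000)
        rows, cols = sample_units(poly, stack.grid, density=0.25)
        proj = unit_table(stack, rows, cols, 2010)
        pool = pe.candidate_pool(stack, poly, proj, 2010)
        got = set(zip(pool["row"], pool["col"]))
        expected = set()
        rr, cc, x, y = stack.grid.all_pixel_centers()
        d = shapely.distance(poly, shapely.points(x, y))
        for r, c, di in zip(rr, cc, d):
            if 5000.0 < di <= 2_000_000.0:
                expected.add((int(r), int(c)))
        assert got == expected

    def test_unit_3km_from_boundary_excluded(self):
        stack = _flat_stack(n=150)
        poly = box(6000, 6000, 8000, 8000)
        rows, cols = sample_units(poly, stack.grid, density=0.25)
        proj = unit_table(stack, rows, cols, 2010)
        pool = pe.candidate_pool(stack, poly, proj, 2010)
        x, y = stack.grid.pixel_centers(pool["row"].to_numpy(), pool["col"].to_numpy())
        pts = shapely.points(x, y)
        assert not shapely.dwithin(poly, pts, 3000.0).any()
        assert not shapely.dwithin(poly, pts, 5000.0).any()

    def test_elevation_tolerance_boundary(self):
        """Candidate at project max + 150 m retained; + 250 m excluded."""
        stack = _flat_stack(n=150)
        r_in, c_in, r_out, c_out = 5, 5, 5, 9
        stack.elevation[r_in, c_in] = 500.0 + 150.0
        stack.elevation[r_out, c_out] = 500.0 + 250.0
        poly = box(6000, 6000, 8000, 8000)
        rows, cols = sample_units(poly, stack.grid, density=0.25)
        proj = unit_table(stack, rows, cols, 2010)  # all at 500 m
        pool = pe.candidate_pool(stack, poly, proj, 2010)
        pairs = set(zip(pool["row"], pool["col"]))
        assert (r_in, c_in) in pairs
        assert (r_out, c_out) not in pairs

    def test_country_mismatch_excluded(self):
        stack = _flat_stack(n=150)
        stack.country[100:, :] = 1  # top rows are another country
        poly = box(6000, 6000, 8000, 8000)  # inside country 0
        rows, cols = sample_units(poly, stack.grid, density=0.25)
        proj = unit_table(stack, rows, cols, 2010)
        pool = pe.candidate_pool(stack, poly, proj, 2010)
        assert (pool["country"] == 0).all()

    def test_empty_pool_raises_with_advice(self):
        stack = _flat_stack(n=150)
        poly = box(6000, 6000, 8000, 8000)
        rows, cols = sample_units(poly, stack.grid, density=0.25)
        proj = unit_table(stack, rows, cols, 2010)
        with pytest.raises(EmptyPoolError, match="distance"):
            pe.candidate_pool(stack, poly, proj, 2010, max_distance_km=0.001)


class TestSmd:
    def test_identical_samples_zero(self):
        x = np.array([1.0, 2.0, 3.0])
        assert pe.smd(x, x) == 0.0

    def test_direct_evaluation(self):
        # means 13.8 vs 25.5, variances 100 and 50 -> -11.7 / sqrt(75)
        rng = np.random.default_rng(0)
        c = rng.normal(size=5000)
        p = rng.normal(size=5000)
        c = (c - c.mean()) / c.std(ddof=1) * 10.0 + 13.8
        p = (p - p.mean()) / p.std(ddof=1) * np.sqrt(50.0) + 25.5
        assert pe.smd(c, p) == pytest.approx(-1.3510, abs=1e-4)

    def test_antisymmetry(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            a, b = rng.normal(size=10), rng.normal(size=12)
            assert pe.smd(a, b) == pytest.approx(-pe.smd(b, a), rel=1e-12)

    def test_zero_variance_flagging(self):
        assert np.isnan(pe.smd([1.0, 1.0], [2.0, 2.0]))  # unequal means: undefined
        assert pe.smd([2.0, 2.0], [2.0, 2.0]) == 0.0  # equal means: balanced

    def test_too_small_samples_rejected(self):
        with pytest.raises(ValueError):
            pe.smd([1.0], [1.0, 2.0])


def regularized_inverse_covariance(x: np.ndarray) -> np.ndarray:
    """Inverse covariance with the documented ridge (1e-6 * trace / d) when
    the covariance is not positive definite."""
    cov = np.atleast_2d(np.cov(x, rowvar=False))
    try:
        np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        d = cov.shape[0]
        cov = cov + max(1e-6 * np.trace(cov) / d, 1e-12) * np.eye(d)
    return np.linalg.inv(cov)


def greedy_oracle(project: pd.DataFrame, pool: pd.DataFrame, order: np.ndarray):
    """Step-by-step re-derivation: explicit Mahalanobis quadratic form,
    exact categorical equality, removal without replacement."""
    xp = project[list(CONTINUOUS_COVARIATES)].to_numpy(float)
    xc = pool[list(CONTINUOUS_COVARIATES)].to_numpy(float)
    sinv = regularized_inverse_covariance(np.vstack([xp, xc]))
    catp = project[list(CATEGORICAL_COVARIATES)].to_numpy()
    catc = pool[list(CATEGORICAL_COVARIATES)].to_numpy()
    used = set()
    pairs, unmatched = [], []
    for i in order:
        best_j, best_d = None, np.inf
        for j in range(len(pool)):
            if j in used or not (catp[i] == catc[j]).all():
                continue
            diff = xp[i] - xc[j]
            d = float(diff @ sinv @ diff)
            if best_j is None or d < best_d - 1e-9 * max(1.0, abs(best_d)):
                best_j, best_d = j, d
            elif abs(d - best_d) <= 1e-9 * max(1.0, abs(best_d)) and (
                pool["row"].iat[j], pool["col"].iat[j]
            ) < (pool["row"].iat[best_j], pool["col"].iat[best_j]):
                best_j, best_d = j, min(d, best_d)
        if best_j is None:
            unmatched.append(int(i))
        else:
            used.add(best_j)
            pairs.append((int(i), best_j))
    return sorted(pairs), sorted(unmatched)


def match_order(n: int, seed: int) -> np.ndarray:
    """The seeded processing order used by the matcher."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), 0x5E])).permutation(n)


class TestGreedyMatch:
    def test_identity_covariance_nearest_euclidean(self):
        rng = np.random.default_rng(1)
        proj = random_unit_frame(rng, 1, n_classes=1)
        pool = random_unit_frame(rng, 2, n_classes=1)
        # place pool unit 0 clearly nearer in covariate space
        for k, name in enumerate(CONTINUOUS_COVARIATES):
            pool.loc[0, name] = proj.loc[0, name] + 0.01
            pool.loc[1, name] = proj.loc[0, name] + 2.0
        ms = pe.greedy_match(proj, pool, seed=0)
        assert ms.pairs.tolist() == [[0, 0]]

    def test_categorical_mismatch_never_matched(self):
        rng = np.random.default_rng(2)
        proj = random_unit_frame(rng, 1, n_classes=1)
        pool = random_unit_frame(rng, 1, n_classes=1)
        for name in CONTINUOUS_COVARIATES:
            pool.loc[0, name] = proj.loc[0, name]  # distance zero
        pool.loc[0, "class_t5"] = 7  # but a different historic class
        ms = pe.greedy_match(proj, pool, seed=0)
        assert ms.n_pairs == 0
        assert ms.unmatched.tolist() == [0]

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_p = int(rng.integers(2, 10))
        n_c = int(rng.integers(n_p, 20))
        proj = random_unit_frame(rng, n_p)
        pool = random_unit_frame(rng, n_c)
        ms = pe.greedy_match(proj, pool, seed=seed)
        pairs, unmatched = greedy_oracle(proj, pool, match_order(n_p, seed))
        assert ms.pairs.tolist() == [list(p) for p in pairs]
        assert ms.unmatched.tolist() == unmatched

    def test_without_replacement_integrity(self):
        rng = np.random.default_rng(5)
        proj = random_unit_frame(rng, 30, n_classes=2)
        pool = random_unit_frame(rng, 60, n_classes=2)
        ms = pe.greedy_match(proj, pool, seed=5)
        controls = ms.pairs[:, 1]
        assert len(np.unique(controls)) == len(controls)

    def test_pairs_agree_on_categoricals(self):
        rng = np.random.default_rng(6)
        proj = random_unit_frame(rng, 25, n_classes=3)
        pool = random_unit_frame(rng, 80, n_classes=3)
        ms = pe.greedy_match(proj, pool, seed=6)
        for i, j in ms.pairs:
            for name in CATEGORICAL_COVARIATES:
                assert proj[name].iat[i] == pool[name].iat[j]

    def test_tie_break_lowest_row_col(self):
        rng = np.random.default_rng(7)
        proj = random_unit_frame(rng, 1, n_classes=1)
        pool = random_unit_frame(rng, 3, n_classes=1)
        for name in CONTINUOUS_COVARIATES:
            pool[name] = proj[name].iat[0]  # all at distance zero
        pool["row"], pool["col"] = [9, 2, 2], [1, 8, 3]
        ms = pe.greedy_match(proj, pool, seed=0)
        assert ms.pairs.tolist() == [[0, 2]]  # (2, 3) is the lowest (row, col)

    def test_accepted_iff_all_smds_within_gate(self, small_units):
        proj, pool = small_units
        sub = proj.sample(60, random_state=0).reset_index(drop=True)
        ms = pe.greedy_match(sub, pool, seed=0)
        within = all(abs(v) <= 0.25 for v in ms.smds.values() if np.isfinite(v))
        no_nan = all(np.isfinite(v) for v in ms.smds.values())
        assert ms.accepted == (within and no_nan)


class TestRunPact:
    def test_balance_gate_and_pair_integrity(self, small_scenario):
        est = pe.run_pact(
            small_scenario.factual,
            small_scenario.project_polygon,
            small_scenario.t0,
            2021,
            config=pe.PactConfig(iterations=20, pool_density=0.25),
            seed=3,
        )
        assert est.n_iterations_accepted >= 1
        for ms in est.matched_sets:
            if ms.accepted:
                assert all(abs(v) <= 0.25 for v in ms.smds.values())
                assert len(np.unique(ms.pairs[:, 1])) == ms.n_pairs
        assert est.avoided_ha_cumulative[0] == 0.0

    def test_known_effect_recovery_single_seed(self, small_scenario):
        est = pe.run_pact(
            small_scenario.factual,
            small_scenario.project_polygon,
            small_scenario.t0,
            2021,
            config=pe.PactConfig(iterations=40, pool_density=0.25),
            seed=4,
        )
        truth = small_scenario.true_avoided_ha
        assert est.avoided_final_ha > 0
        assert abs(est.avoided_final_ha - truth) / truth < 0.6  # single small seed: loose

    def test_all_rejected_raises_with_report(self, small_scenario):
        with pytest.raises(AllIterationsRejectedError, match="balance"):
            pe.run_pact(
                small_scenario.factual,
                small_scenario.project_polygon,
                small_scenario.t0,
                2021,
                config=pe.PactConfig(iterations=5, pool_density=0.25, smd_threshold=1e-9),
                seed=5,
            )

    def test_horizon_validation(self, small_scenario):
        with pytest.raises(ValueError, match="horizon"):
            pe.run_pact(
                small_scenario.factual, small_scenario.project_polygon,
                small_scenario.t0, small_scenario.t0, seed=1,
            )
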