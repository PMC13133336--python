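"""Synthetic landscapes with known deforestation processes and counterfactuals.

The generator builds the world the estimator is validated against: spatially
autocorrelated covariates, a per-pixel annual deforestation hazard driven by
those covariates, systematically biased siting of project versus reference
areas, a multiplicative treatment effect after the project start, and paired
factual/counterfactual land-cover series simulated from common random numbers
so the two arms differ only through the treatment.

Because the counterfactual arm is simulated explicitly, the true avoided
deforestation of every scenario is known exactly — which is what makes the
downstream matching estimator testable without any real data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, uniform_filter
from scipy.special import expit, logit
from shapely.geometry import Polygon, box

from .grids import GridSpec, LandCover, LandscapeStack
from .rates import compound_rate

__all__ = [
    "HazardModel",
    "ScenarioTruth",
    "generate_covariates",
    "hazard_probability",
    "place_polygons",
    "simulate_landcover",
    "make_scenario",
]

log = logging.getLogger(__name__)

#: Years a disturbed pixel spends in the DEGRADED class before REGROWTH.
#: Short disturbances last under 2.5 years; recovery is classed as regrowth
#: from the third year after disturbance onward.
DEGRADATION_WINDOW = 2


@dataclass(frozen=True)
class HazardModel:
    """Annual per-pixel deforestation hazard on the logit scale.

    The hazard is ``expit(intercept + sum(coef * z) + noise)`` where ``z`` are
    grid-standardised covariates and ``noise`` is a static pixel-level
    log-odds field representing drivers the covariates do not capture.

    Coefficient signs follow the usual exposure gradient: deforestation
    pressure rises toward low elevation, gentle slopes and short travel times
    to population centres, hence all three default slopes are negative.

    ``treatment_multiplier`` scales the hazard inside the project after the
    start year (1.0 means the project changes nothing).
    ``degradation_fraction`` is the probability that a disturbance is
    short-term (degradation then regrowth) rather than permanent clearing.
    """

    intercept: float = float(logit(0.02))
    coefficients: tuple[tuple[str, float], ...] = (
        ("elevation", -0.4),
        ("slope", -0.3),
        ("accessibility", -0.5),
    )
    spatial_noise_sd: float = 0.1
    treatment_multiplier: float = 0.5
    degradation_fraction: float = 0.3

    def __post_init__(self) -> None:
        if not 0.0 <= self.treatment_multiplier <= 1.0:
            raise ValueError("treatment_multiplier must lie in [0, 1]")
        if not 0.0 <= self.degradation_fraction <= 1.0:
            raise ValueError("degradation_fraction must lie in [0, 1]")
        if self.spatial_noise_sd < 0:
            raise ValueError("spatial_noise_sd must be >= 0")


@dataclass
class ScenarioTruth:
    """A simulated scenario together with its exact ground truth.

    ``factual`` and ``counterfactual`` share every layer and every random
    draw; they are identical for all years up to and including ``t0`` and
    outside the project polygon at all times.  ``truth_table`` holds per-year
    undisturbed areas (ha) inside the project for both arms and their
    difference, the cumulative avoided deforestation.
    """

    factual: LandscapeStack
    counterfactual: LandscapeStack
    project_polygon: Polygon
    reference_polygon: Polygon | None
    t0: int
    truth_table: pd.DataFrame
    true_avoided_ha: float
    true_avoided_rate: float  # %/year, counterfactual minus factual compound rate
    hazard: HazardModel = field(default=None)  # type: ignore[assignment]


def _smooth_field(shape: tuple[int, int], sigma_px: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian-filtered white noise, scaled to ~unit variance for sigma << grid.

    The analytic amplitude ``2 sqrt(pi) sigma`` undoes the variance shrinkage
    of the filter; as the length-scale grows beyond the grid the field
    flattens toward a constant (its spatial variance tends to zero), which is
    the intended limiting behaviour.
    """
    noise = rng.standard_normal(shape)
    if sigma_px <= 0:
        return noise
    f = gaussian_filter(noise, sigma=sigma_px, mode="reflect")
    return f * (2.0 * np.sqrt(np.pi) * sigma_px)


def _nearest_seed_partition(
    shape: tuple[int, int], n_regions: int, rng: np.random.Generator
) -> np.ndarray:
    """Contiguous categorical partition: label = nearest of n random seed points."""
    n_rows, n_cols = shape
    seeds_r = rng.uniform(0, n_rows, size=n_regions)
    seeds_c = rng.uniform(0, n_cols, size=n_regions)
    rows, cols = np.indices(shape)
    d2 = (rows[..., None] - seeds_r) ** 2 + (cols[..., None] - seeds_c) ** 2
    return np.argmin(d2, axis=-1).astype(np.int16)


def generate_covariates(
    grid: GridSpec,
    smoothness: float = 500.0,
    seed: int = 0,
    n_countries: int = 1,
    n_ecoregions: int = 3,
) -> LandscapeStack:
    """Generate spatially autocorrelated covariate layers.

    Parameters
    ----------
    grid
        Target grid; dimensions are validated by :class:`GridSpec`.
    smoothness
        Autocorrelation length-scale in metres (> 0).  Larger values give
        smoother fields; in the infinite limit every field is constant.
    seed
        Root seed; identical (grid, smoothness, seed) gives bit-identical
        layers.
    n_countries, n_ecoregions
        Number of contiguous categorical regions to carve the grid into.

    Returns
    -------
    LandscapeStack
        Covariates only (empty land-cover series).
    """
    if smoothness <= 0:
        raise ValueError(f"smoothness must be > 0, got {smoothness}")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x1A]))
    sigma_px = smoothness / grid.pixel_size

    f_elev = _smooth_field(grid.shape, sigma_px, rng)
    f_acc = _smooth_field(grid.shape, sigma_px, rng)

    elevation = np.maximum(0.0, 500.0 + 300.0 * f_elev)
    # slope from the elevation surface itself, so the two covary realistically
    gy, gx = np.gradient(elevation, grid.pixel_size)
    slope = np.degrees(np.arctan(np.hypot(gx, gy)))
    slope = np.clip(slope, 0.0, 90.0)
    # travel time to the nearest population centre, minutes; log-normal-ish
    accessibility = 60.0 * np.exp(0.9 * np.clip(f_acc, -4.0, 4.0))

    country = _nearest_seed_partition(grid.shape, n_countries, rng)
    ecoregion = _nearest_seed_partition(grid.shape, n_ecoregions, rng)

    return LandscapeStack(
        grid=grid,
        elevation=elevation,
        slope=slope,
        accessibility=accessibility,
        country=country,
        ecoregion=ecoregion,
    )


def _standardize(layer: np.ndarray) -> np.ndarray:
    sd = layer.std()
    return (layer - layer.mean()) / sd if sd > 0 else np.zeros_like(layer)


def hazard_probability(
    stack: LandscapeStack, model: HazardModel, noise_seed: int = 0
) -> np.ndarray:
    """Per-pixel annual hazard of leaving the undisturbed class, in (0, 1).

    The static noise field is drawn from ``noise_seed`` alone, so polygon
    placement and land-cover simulation agree on the same hazard surface when
    given the same seed.
    """
    eta = np.full(stack.grid.shape, model.intercept, dtype=float)
    for name, coef in model.coefficients:
        eta += coef * _standardize(getattr(stack, name))
    if model.spatial_noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence([int(noise_seed), 0x2B]))
        eta += model.spatial_noise_sd * rng.standard_normal(stack.grid.shape)
    return np.clip(expit(eta), 1e-9, 1.0 - 1e-9)


def rasterize_polygon(polygon: Polygon, grid: GridSpec) -> np.ndarray:
    """Boolean mask of pixels whose centres fall inside the polygon."""
    import shapely

    rows, cols, x, y = grid.all_pixel_centers()
    inside = shapely.contains_xy(polygon, x, y)
    mask = np.zeros(grid.shape, dtype=bool)
    mask[rows[inside], cols[inside]] = True
    return mask


def _pixel_rect_polygon(grid: GridSpec, r0: int, c0: int, height: int, width: int) -> Polygon:
    x0, y0 = grid.origin
    return box(
        x0 + c0 * grid.pixel_size,
        y0 + r0 * grid.pixel_size,
        x0 + (c0 + width) * grid.pixel_size,
        y0 + (r0 + height) * grid.pixel_size,
    )


def place_polygons(
    stack: LandscapeStack,
    hazard: HazardModel,
    siting_bias: float = 0.5,
    seed: int = 0,
    noise_seed: int | None = None,
    project_shape: tuple[int, int] | None = None,
    reference_shape: tuple[int, int] | None = None,
) -> tuple[Polygon, Polygon]:
    """Site disjoint project and reference rectangles by neighbourhood hazard.

    The project is centred in a neighbourhood whose mean hazard is at or
    below the ``siting_bias`` quantile of candidate neighbourhoods, the
    reference area in one at or above the ``1 - siting_bias`` quantile — the
    systematic siting bias observed for real projects, whose reference areas
    were more exposed to deforestation drivers than the projects themselves.
    ``siting_bias = 0`` pins the project to the minimum-hazard neighbourhood.
    """
    if not 0.0 <= siting_bias <= 1.0:
        raise ValueError("siting_bias must lie in [0, 1]")
    grid = stack.grid
    if project_shape is None:
        project_shape = (max(1, grid.n_rows // 5), max(1, grid.n_cols // 5))
    if reference_shape is None:
        reference_shape = project_shape
    ph, pw = project_shape
    rh, rw = reference_shape
    if ph + rh > grid.n_rows and pw + rw > grid.n_cols:
        raise ValueError(
            f"grid {grid.shape} too small to host disjoint project {project_shape} "
            f"and reference {reference_shape} polygons"
        )

    p = hazard_probability(stack, hazard, seed if noise_seed is None else noise_seed)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x3C]))

    def _candidates(h: int, w: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        # padding value never enters: only fully interior centres are kept below
        mean_h = uniform_filter(p, size=(h, w), mode="constant", cval=0.0)
        rows = np.arange(h // 2, grid.n_rows - (h - 1) // 2 - 1 + 1)
        cols = np.arange(w // 2, grid.n_cols - (w - 1) // 2 - 1 + 1)
        rr, cc = np.meshgrid(rows, cols, indexing="ij")
        vals = mean_h[rr, cc]
        ok = np.isfinite(vals)
        return rr[ok], cc[ok], vals[ok]

    rr, cc, vals = _candidates(ph, pw)
    if rr.size == 0:
        raise ValueError(f"grid {grid.shape} too small for project polygon {project_shape}")
    thr = np.quantile(vals, siting_bias)
    low = np.flatnonzero(vals <= thr)
    pick = low[rng.integers(low.size)] if siting_bias > 0 else int(np.argmin(vals))
    pr, pc = int(rr[pick]), int(cc[pick])
    pr0, pc0 = pr - ph // 2, pc - pw // 2
    project = _pixel_rect_polygon(grid, pr0, pc0, ph, pw)

    rr2, cc2, vals2 = _candidates(rh, rw)
    # exclude reference centres whose rectangle would touch the project's
    sep_r, sep_c = (ph + rh) // 2 + 1, (pw + rw) // 2 + 1
    disjoint = (np.abs(rr2 - pr) >= sep_r) | (np.abs(cc2 - pc) >= sep_c)
    if not np.any(disjoint):
        raise ValueError(f"grid {grid.shape} too small to host disjoint polygons")
    rr2, cc2, vals2 = rr2[disjoint], cc2[disjoint], vals2[disjoint]
    thr2 = np.quantile(vals2, 1.0 - siting_bias)
    high = np.flatnonzero(vals2 >= thr2)
    pick2 = high[rng.integers(high.size)] if siting_bias > 0 else int(np.argmax(vals2))
    rr0, rc0 = int(rr2[pick2]) - rh // 2, int(cc2[pick2]) - rw // 2
    reference = _pixel_rect_polygon(grid, rr0, rc0, rh, rw)
    return project, reference


def simulate_landcover(
    stack: LandscapeStack,
    hazard: HazardModel,
    years: tuple[int, int],
    t0: int,
    project_polygon: Polygon,
    seed: int = 0,
    noise_seed: int | None = None,
    reference_polygon: Polygon | None = None,
    water_mask: np.ndarray | None = None,
) -> ScenarioTruth:
    """Simulate paired factual/counterfactual annual land-cover series.

    Per pixel-year an undisturbed pixel converts with probability equal to
    its hazard (times ``treatment_multiplier`` inside the project after
    ``t0``, factual arm only).  A converting pixel becomes degraded —
    reverting to regrowth after the degradation window — with probability
    ``degradation_fraction``, else permanently deforested.  Both arms consume
    the same uniform draws, so they differ only through the treatment and
    the counterfactual never keeps less forest than the factual arm.
    """
    y_min, y_max = int(years[0]), int(years[1])
    if not (y_min < t0 < y_max):
        raise ValueError(f"t0={t0} must lie strictly inside the simulated years [{y_min}, {y_max}]")
    grid = stack.grid
    n_years = y_max - y_min + 1
    year_seq = np.arange(y_min, y_max + 1)

    project_mask = rasterize_polygon(project_polygon, grid)
    m = hazard.treatment_multiplier
    p_base = hazard_probability(stack, hazard, seed if noise_seed is None else noise_seed)

    init = np.full(grid.shape, LandCover.UNDISTURBED, dtype=np.uint8)
    if water_mask is not None:
        init[water_mask] = LandCover.WATER

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x4D]))

    def _alloc() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        lc = np.empty((n_years, *grid.shape), dtype=np.uint8)
        lc[0] = init
        state = init.copy()
        deg_age = np.zeros(grid.shape, dtype=np.int16)  # years since degradation event
        return lc, state, deg_age

    lc_f, state_f, age_f = _alloc()
    lc_c, state_c, age_c = _alloc()

    for i, year in enumerate(year_seq[1:], start=1):
        u = rng.random(grid.shape)
        v = rng.random(grid.shape)
        treated = year > t0
        for arm, state, age, lc in (("f", state_f, age_f, lc_f), ("c", state_c, age_c, lc_c)):
            p_eff = p_base
            if arm == "f" and treated and m != 1.0:
                p_eff = np.where(project_mask, p_base * m, p_base)
            convert = (state == LandCover.UNDISTURBED) & (u < p_eff)
            short = convert & (v < hazard.degradation_fraction)
            state[convert & ~short] = LandCover.DEFORESTED
            state[short] = LandCover.DEGRADED
            age[short] = 0
            aging = (state == LandCover.DEGRADED) & ~short
            age[aging] += 1
            state[aging & (age >= DEGRADATION_WINDOW)] = LandCover.REGROWTH
            lc[i] = state

    factual = stack.with_landcover(lc_f, year_seq)
    counterfactual = stack.with_landcover(lc_c, year_seq)

    n_proj = int(project_mask.sum())
    und_f = (lc_f[:, project_mask] == LandCover.UNDISTURBED).sum(axis=1) * grid.pixel_area
    und_c = (lc_c[:, project_mask] == LandCover.UNDISTURBED).sum(axis=1) * grid.pixel_area
    truth = pd.DataFrame(
        {
            "year": year_seq,
            "factual_undisturbed_ha": und_f,
            "counterfactual_undisturbed_ha": und_c,
            "avoided_ha": und_f - und_c,
        }
    )
    i0 = int(np.flatnonzero(year_seq == t0)[0])
    t_span = y_max - t0
    f0_f, ft_f = float(und_f[i0]), float(und_f[-1])
    f0_c, ft_c = float(und_c[i0]), float(und_c[-1])
    if f0_f > 0 and ft_f > 0 and f0_c > 0 and ft_c > 0:
        rate = (compound_rate(f0_c, ft_c, t_span) - compound_rate(f0_f, ft_f, t_span)) * 100.0
    else:
        rate = float("nan")
    log.info(
        "simulated scenario: %d project pixels, t0=%d, horizon %d yr, true avoided %.1f ha",
        n_proj, t0, t_span, float(und_f[-1] - und_c[-1]),
    )
    return ScenarioTruth(
        factual=factual,
        counterfactual=counterfactual,
        project_polygon=project_polygon,
        reference_polygon=reference_polygon,
        t0=t0,
        truth_table=truth,
        true_avoided_ha=float(und_f[-1] - und_c[-1]),
        true_avoided_rate=float(rate),
        hazard=hazard,
    )


def make_scenario(
    grid: GridSpec | None = None,
    hazard: HazardModel | None = None,
    years: tuple[int, int] = (1999, 2021),
    t0: int = 2011,
    siting_bias: float = 0.5,
    smoothness: float = 1000.0,
    project_shape: tuple[int, int] = (100, 100),
    seed: int = 0,
    n_ecoregions: int = 3,
) -> ScenarioTruth:
    """One-call scenario builder: covariates, siting, paired simulation.

    Defaults define the known-effect validation scenario: a 600x600 grid of
    100 m cells, a 100x100-pixel (10^4 ha) project, mean hazard near 2%/yr,
    treatment multiplier 0.5, and a 10-year monitoring horizon after ``t0``
    with 12 years of pre-project history for the matching covariates.  The
    landscape is dimensioned so the untreated domain holds many covariate
    patches comparable to the project (the real matching domain spans up to
    2000 km); a 1 km covariate length-scale gives hundreds of independent
    patches.

    All randomness derives from ``seed``; the hazard noise field is shared
    between polygon placement and both simulation arms.
    """
    if grid is None:
        grid = GridSpec(n_rows=600, n_cols=600, pixel_size=100.0)
    if hazard is None:
        hazard = HazardModel()
    ss = np.random.SeedSequence(int(seed))
    s_cov, s_place, s_dyn = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3))
    stack = generate_covariates(grid, smoothness=smoothness, seed=s_cov, n_ecoregions=n_ecoregions)
    project, reference = place_polygons(
        stack, hazard, siting_bias=siting_bias, seed=s_place, noise_seed=s_dyn,
        project_shape=project_shape,
    )
    return simulate_landcover(
        stack, hazard, years, t0, project, seed=s_dyn, noise_seed=s_dyn,
        reference_polygon=reference,
    )
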