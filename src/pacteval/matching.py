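"""The PACT pixel-matching estimator of avoided deforestation.

PACT (Permanent Additional Carbon Tonne, v2) estimates the counterfactual
forest trajectory of a project by pairing sampled project pixels with
untreated pixels that look the same before the project starts.  The steps,
each exposed as its own operation:

1. :func:`sample_units` — lay a regular point lattice over the project at
   0.25 pt/ha (0.05 pt/ha above 250,000 ha) and snap to pixel centres.
2. :func:`proportional_cover` — for each pixel, the fraction of a 1 km-radius
   disc neighbourhood occupied by a given land-cover class; extracted at the
   project start t0 and five and ten years earlier as trajectory covariates.
3. :func:`candidate_pool` — untreated pixels in the project's countries and
   ecoregions, at least 5 km from every project but within 2000 km of the
   focal one, and inside the project's covariate ranges plus fixed tolerances.
4. :func:`greedy_match` — 1:1 nearest-Mahalanobis matching without
   replacement, exact on the categorical covariates, over a seeded random
   processing order.
5. The standardised-mean-difference gate: iterations where any continuous
   covariate's |SMD| exceeds 0.25 are discarded as unbalanced.
6. :func:`run_pact` — 100 such iterations on fresh 10% project subsamples;
   undisturbed proportions times project area give per-year project and
   counterfactual forest areas, averaged over accepted iterations into a
   cumulative avoided-deforestation series.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy.linalg import solve_triangular
from scipy.ndimage import convolve as ndi_convolve
from scipy.signal import oaconvolve
from scipy.spatial.distance import cdist
from shapely.geometry import Polygon

from .grids import GridSpec, LandCover, LandscapeStack

__all__ = [
    "CONTINUOUS_COVARIATES",
    "CATEGORICAL_COVARIATES",
    "Tolerances",
    "PactConfig",
    "MatchedSet",
    "PactEstimate",
    "EmptyPoolError",
    "AllIterationsRejectedError",
    "sample_units",
    "auto_density",
    "proportional_cover",
    "unit_table",
    "candidate_pool",
    "smd",
    "greedy_match",
    "run_pact",
]

log = logging.getLogger(__name__)

CONTINUOUS_COVARIATES = (
    "elevation",
    "slope",
    "accessibility",
    "prop_undisturbed_t0",
    "prop_undisturbed_t5",
    "prop_undisturbed_t10",
    "prop_deforested_t0",
    "prop_deforested_t5",
    "prop_deforested_t10",
)
CATEGORICAL_COVARIATES = ("country", "ecoregion", "class_t0", "class_t5", "class_t10")

#: Project-size threshold (ha) above which the sparser sampling density applies.
LARGE_PROJECT_HA = 250_000.0
DENSITY_SMALL = 0.25  # points per ha
DENSITY_LARGE = 0.05


class EmptyPoolError(RuntimeError):
    """Raised when candidate filtering leaves no untreated units."""


class AllIterationsRejectedError(RuntimeError):
    """Raised when every matching iteration fails the balance gate."""


@dataclass(frozen=True)
class Tolerances:
    """Half-widths added to the project's observed covariate ranges when
    filtering candidates: +/-200 m elevation, +/-2.5 deg slope, +/-10 min
    accessibility, +/-10 percentage points proportional cover."""

    elevation: float = 200.0
    slope: float = 2.5
    accessibility: float = 10.0
    proportional_cover: float = 0.10

    def __post_init__(self) -> None:
        for name in ("elevation", "slope", "accessibility", "proportional_cover"):
            if getattr(self, name) < 0:
                raise ValueError(f"tolerance {name} must be non-negative")

    def for_covariate(self, name: str) -> float:
        if name.startswith("prop_"):
            return self.proportional_cover
        return getattr(self, name)


@dataclass(frozen=True)
class PactConfig:
    """Tunable parameters of a PACT run (defaults are the standard protocol)."""

    iterations: int = 100
    sample_fraction: float = 0.10
    smd_threshold: float = 0.25
    min_pairs: int = 30  # small-sample guard: reject iterations below this
    density: float | None = None  # points/ha; None = auto by project size
    pool_density: float | None = None  # None = every eligible pixel
    min_distance_km: float = 5.0
    max_distance_km: float = 2000.0
    tolerances: Tolerances = field(default_factory=Tolerances)


@dataclass
class MatchedSet:
    """One iteration's pairing plus its balance report.

    ``pairs`` maps positional indices of the project subsample to positional
    indices of the pool table; ``smds`` holds the per-covariate standardised
    mean differences of the matched controls against the matched project
    units; ``accepted`` is True iff every |SMD| is within the gate.
    """

    iteration: int
    pairs: np.ndarray  # (n_pairs, 2) [project_idx, pool_idx]
    unmatched: np.ndarray  # project indices with no exact-categorical candidate
    smds: dict[str, float]
    accepted: bool
    rejection_reason: str | None = None

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def balance_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "iteration": self.iteration,
                "covariate": list(self.smds),
                "smd": list(self.smds.values()),
                "accepted": self.accepted,
            }
        )


@dataclass
class PactEstimate:
    """Aggregated PACT outcome series.

    Areas are hectares; ``avoided_ha_cumulative`` is the divergence of the
    project and counterfactual undisturbed areas since t0 (zero at t0 by
    construction, since pairs agree exactly on the t0 land-cover class).
    """

    years: np.ndarray
    project_ha: np.ndarray
    counterfactual_ha: np.ndarray
    avoided_ha_cumulative: np.ndarray
    n_iterations_accepted: int
    iteration_final_avoided: np.ndarray  # per accepted iteration, last year
    matched_sets: list[MatchedSet]

    @property
    def avoided_final_ha(self) -> float:
        return float(self.avoided_ha_cumulative[-1])

    def iteration_interval(self, level: float = 0.95) -> tuple[float, float]:
        """Percentile interval of the final avoided value across iterations."""
        a = (1.0 - level) / 2.0
        lo, hi = np.quantile(self.iteration_final_avoided, [a, 1.0 - a])
        return float(lo), float(hi)

    def series_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "year": self.years,
                "project_ha": self.project_ha,
                "counterfactual_ha": self.counterfactual_ha,
                "avoided_ha_cumulative": self.avoided_ha_cumulative,
            }
        )


def auto_density(area_ha: float) -> float:
    """Sampling density rule: 0.25 pt/ha below 250,000 ha, 0.05 pt/ha above."""
    return DENSITY_SMALL if area_ha < LARGE_PROJECT_HA else DENSITY_LARGE


def sample_units(
    polygon: Polygon, grid: GridSpec, density: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Regular lattice of sample pixels inside a polygon.

    Points are laid on a square lattice with spacing ``sqrt(1/density)``
    (offset half a spacing from the polygon envelope), snapped to the pixel
    containing them, and kept only where the pixel centre lies inside the
    polygon and on the grid.  Returns (rows, cols).
    """
    area_ha = polygon.area / 10_000.0
    if density is None:
        density = auto_density(area_ha)
    if not density > 0:
        raise ValueError(f"density must be > 0, got {density}")
    spacing = np.sqrt(10_000.0 / density)  # metres between lattice points
    minx, miny, maxx, maxy = polygon.bounds
    xs = np.arange(minx + spacing / 2.0, maxx, spacing)
    ys = np.arange(miny + spacing / 2.0, maxy, spacing)
    if xs.size == 0 or ys.size == 0:
        raise ValueError("polygon does not intersect the sampling lattice")
    xx, yy = np.meshgrid(xs, ys)
    rows, cols = grid.point_to_pixel(xx.ravel(), yy.ravel())
    ok = grid.in_grid(rows, cols)
    rows, cols = rows[ok], cols[ok]
    # unique pixels (snapping can collide when spacing < pixel size)
    flat = np.unique(rows * grid.n_cols + cols)
    rows, cols = flat // grid.n_cols, flat % grid.n_cols
    cx, cy = grid.pixel_centers(rows, cols)
    inside = shapely.contains_xy(polygon, cx, cy)
    rows, cols = rows[inside], cols[inside]
    if rows.size == 0:
        raise ValueError(f"no sample pixels fall inside polygon with bounds {polygon.bounds}")
    return rows, cols


def _disc_kernel(radius_m: float, pixel_size: float) -> np.ndarray:
    r_px = int(np.floor(radius_m / pixel_size))
    dr = np.arange(-r_px, r_px + 1)
    dd = dr[:, None] ** 2 + dr[None, :] ** 2
    return (dd * pixel_size**2 <= radius_m**2).astype(float)


def proportional_cover(
    landcover_layer: np.ndarray,
    cls: LandCover | int,
    pixel_size: float,
    radius: float = 1000.0,
) -> np.ndarray:
    """Fraction of the disc neighbourhood around each pixel in a class.

    The neighbourhood is the set of pixels whose centres lie within
    ``radius`` metres of the focal pixel centre; at grid edges the
    denominator shrinks to the in-grid pixel count.
    """
    cls = int(cls)
    if cls not in set(int(c) for c in LandCover):
        raise ValueError(f"unknown land-cover class code {cls}")
    if radius < pixel_size:
        raise ValueError(f"radius {radius} m must be >= pixel size {pixel_size} m")
    kernel = _disc_kernel(radius, pixel_size)
    indicator = (landcover_layer == cls).astype(float)
    if kernel.shape[0] <= 15:
        num = ndi_convolve(indicator, kernel, mode="constant", cval=0.0)
        den = ndi_convolve(np.ones_like(indicator), kernel, mode="constant", cval=0.0)
    else:
        num = oaconvolve(indicator, kernel, mode="same")
        den = oaconvolve(np.ones_like(indicator), kernel, mode="same")
    return np.clip(num / den, 0.0, 1.0)


def _epoch_years(stack: LandscapeStack, t0: int) -> dict[str, int]:
    """Calendar years for the t0 / t-5 / t-10 covariate epochs (clamped to series)."""
    return {
        "t0": stack.nearest_year(t0),
        "t5": stack.nearest_year(t0 - 5),
        "t10": stack.nearest_year(t0 - 10),
    }


def epoch_cover_rasters(stack: LandscapeStack, t0: int, radius: float = 1000.0) -> dict[str, np.ndarray]:
    """Proportional-cover rasters for undisturbed/deforested at the three epochs."""
    rasters: dict[str, np.ndarray] = {}
    for tag, year in _epoch_years(stack, t0).items():
        layer = stack.landcover_in(year)
        rasters[f"prop_undisturbed_{tag}"] = proportional_cover(
            layer, LandCover.UNDISTURBED, stack.grid.pixel_size, radius
        )
        rasters[f"prop_deforested_{tag}"] = proportional_cover(
            layer, LandCover.DEFORESTED, stack.grid.pixel_size, radius
        )
    return rasters


def unit_table(
    stack: LandscapeStack,
    rows: np.ndarray,
    cols: np.ndarray,
    t0: int,
    cover_rasters: dict[str, np.ndarray] | None = None,
    nodata_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Sample-unit covariate table for the given pixels.

    Continuous covariates: elevation, slope, accessibility and the six
    proportional-cover values; categorical: country, ecoregion and the
    land-cover class at t0, t-5 and t-10.  Units on nodata pixels are
    dropped (and counted in the log).
    """
    if cover_rasters is None:
        cover_rasters = epoch_cover_rasters(stack, t0)
    if nodata_mask is not None:
        keep = ~nodata_mask[rows, cols]
        n_drop = int((~keep).sum())
        if n_drop:
            log.info("dropping %d sample units on nodata pixels", n_drop)
        rows, cols = rows[keep], cols[keep]
    data = {
        "row": rows,
        "col": cols,
        "elevation": stack.elevation[rows, cols],
        "slope": stack.slope[rows, cols],
        "accessibility": stack.accessibility[rows, cols],
        "country": stack.country[rows, cols],
        "ecoregion": stack.ecoregion[rows, cols],
    }
    for name, raster in cover_rasters.items():
        data[name] = raster[rows, cols]
    for tag, year in _epoch_years(stack, t0).items():
        data[f"class_{tag}"] = stack.landcover_in(year)[rows, cols]
    df = pd.DataFrame(data)
    bad = ~np.isfinite(df[list(CONTINUOUS_COVARIATES)].to_numpy(float)).all(axis=1)
    if bad.any():
        log.info("dropping %d sample units with non-finite covariates", int(bad.sum()))
        df = df.loc[~bad].reset_index(drop=True)
    return df


def candidate_pool(
    stack: LandscapeStack,
    project_polygon: Polygon,
    project_units: pd.DataFrame,
    t0: int,
    all_project_polygons: list[Polygon] | None = None,
    min_distance_km: float = 5.0,
    max_distance_km: float = 2000.0,
    tolerances: Tolerances | None = None,
    pool_density: float | None = None,
    cover_rasters: dict[str, np.ndarray] | None = None,
    nodata_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Untreated candidate units eligible to serve as controls.

    Candidates must (i) share a country and an ecoregion with the project
    sample, (ii) lie at least ``min_distance_km`` from every project polygon
    (leakage guard), (iii) lie within ``max_distance_km`` of the focal
    project, and (iv) fall inside the project's observed [min, max] range,
    widened by the fixed tolerances, for every continuous covariate.
    """
    if tolerances is None:
        tolerances = Tolerances()
    if all_project_polygons is None:
        all_project_polygons = [project_polygon]
    grid = stack.grid

    if pool_density is None:
        rows, cols, x, y = grid.all_pixel_centers()
    else:
        rows, cols = sample_units(shapely.box(*grid.extent), grid, density=pool_density)
        x, y = grid.pixel_centers(rows, cols)

    pts = shapely.points(x, y)
    near_any = np.zeros(len(pts), dtype=bool)
    for poly in all_project_polygons:
        near_any |= shapely.dwithin(poly, pts, min_distance_km * 1000.0)
    within_max = shapely.dwithin(project_polygon, pts, max_distance_km * 1000.0)
    keep = ~near_any & within_max
    rows, cols = rows[keep], cols[keep]
    if rows.size == 0:
        raise EmptyPoolError(
            "no untreated pixels remain after the distance filters; "
            "consider relaxing min/max distance"
        )

    countries = set(np.unique(project_units["country"]))
    ecoregions = set(np.unique(project_units["ecoregion"]))
    ok = np.isin(stack.country[rows, cols], list(countries)) & np.isin(
        stack.ecoregion[rows, cols], list(ecoregions)
    )
    rows, cols = rows[ok], cols[ok]
    if rows.size == 0:
        raise EmptyPoolError("no untreated pixels share the project's country/ecoregion set")

    pool = unit_table(stack, rows, cols, t0, cover_rasters=cover_rasters, nodata_mask=nodata_mask)
    n_before = len(pool)
    for name in CONTINUOUS_COVARIATES:
        tol = tolerances.for_covariate(name)
        lo = project_units[name].min() - tol
        hi = project_units[name].max() + tol
        pool = pool[(pool[name] >= lo) & (pool[name] <= hi)]
    pool = pool.reset_index(drop=True)
    log.info("candidate pool: %d of %d units survive covariate-range filters", len(pool), n_before)
    if pool.empty:
        raise EmptyPoolError(
            "covariate-range filters left an empty candidate pool; "
            "relax the tolerances or widen the search distances"
        )
    return pool


def smd(control: np.ndarray, project: np.ndarray) -> float:
    """Standardised mean difference (control minus project).

    ``(mean_c - mean_p) / sqrt((var_c + var_p) / 2)`` with n-1 variances.
    With zero pooled variance the SMD is undefined: equal means return 0.0
    (trivially balanced), unequal means return NaN (flagged unbalanced).
    """
    control = np.asarray(control, dtype=float)
    project = np.asarray(project, dtype=float)
    if control.size < 2 or project.size < 2:
        raise ValueError("both samples need at least 2 values")
    mc, mp = control.mean(), project.mean()
    pooled = (control.var(ddof=1) + project.var(ddof=1)) / 2.0
    if pooled == 0.0:
        return 0.0 if mc == mp else float("nan")
    return float((mc - mp) / np.sqrt(pooled))


def _categorical_keys(project: pd.DataFrame, pool: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Encode the exact-match categorical tuple of each unit as one integer."""
    both = pd.concat(
        [project[list(CATEGORICAL_COVARIATES)], pool[list(CATEGORICAL_COVARIATES)]],
        ignore_index=True,
    )
    codes = pd.factorize(pd.MultiIndex.from_frame(both))[0]
    return codes[: len(project)], codes[len(project):]


def _regularized_cholesky(x_union: np.ndarray) -> np.ndarray:
    """Lower Cholesky factor of the covariance, ridged if singular."""
    cov = np.cov(x_union, rowvar=False)
    cov = np.atleast_2d(cov)
    d = cov.shape[0]
    try:
        return np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        ridge = 1e-6 * np.trace(cov) / d
        if ridge <= 0:
            ridge = 1e-12
        log.warning("singular matching covariance; adding ridge %.3g to the diagonal", ridge)
        return np.linalg.cholesky(cov + ridge * np.eye(d))


class MatchingContext:
    """Precomputed matching state shared across bootstrap iterations.

    Whitens the continuous covariates with the Cholesky factor of their
    covariance over the union of the (full) project sample and the candidate
    pool, so squared Euclidean distance in the whitened space equals squared
    Mahalanobis distance, and encodes each unit's categorical tuple as one
    integer key for the exact-match constraint.
    """

    def __init__(self, project_units: pd.DataFrame, pool_units: pd.DataFrame):
        self.project_units = project_units
        self.pool_units = pool_units
        xp = project_units[list(CONTINUOUS_COVARIATES)].to_numpy(float)
        xc = pool_units[list(CONTINUOUS_COVARIATES)].to_numpy(float)
        chol = _regularized_cholesky(np.vstack([xp, xc]))
        self.xp, self.xc = xp, xc
        self.wp = solve_triangular(chol, xp.T, lower=True).T
        self.wc = solve_triangular(chol, xc.T, lower=True).T if len(xc) else xc
        self.keys_p, self.keys_c = _categorical_keys(project_units, pool_units)
        self.pool_rc = pool_units[["row", "col"]].to_numpy(int)
        self.by_key: dict[int, np.ndarray] = {
            int(k): np.flatnonzero(self.keys_c == k) for k in np.unique(self.keys_c)
        }


def _greedy_from_context(
    ctx: MatchingContext,
    sub_idx: np.ndarray,
    seed: int,
    iteration: int,
    smd_threshold: float,
) -> MatchedSet:
    """Greedy pass over one project subsample using precomputed state."""
    n_sub = len(sub_idx)
    keys_sub = ctx.keys_p[sub_idx]
    wp_sub = ctx.wp[sub_idx]

    # one distance matrix per categorical group present in the subsample
    dist: dict[int, np.ndarray] = {}
    sub_row_in_group: dict[int, dict[int, int]] = {}
    for key in np.unique(keys_sub):
        cand = ctx.by_key.get(int(key))
        if cand is None:
            continue
        members = np.flatnonzero(keys_sub == key)
        dist[int(key)] = cdist(wp_sub[members], ctx.wc[cand], "sqeuclidean")
        sub_row_in_group[int(key)] = {int(m): r for r, m in enumerate(members)}

    used = np.zeros(len(ctx.pool_units), dtype=bool)
    order = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5E])).permutation(n_sub)
    pairs: list[tuple[int, int]] = []
    unmatched: list[int] = []
    for i in order:
        key = int(keys_sub[i])
        cand = ctx.by_key.get(key)
        if cand is not None:
            free = ~used[cand]
            cand = cand[free]
        if cand is None or cand.size == 0:
            unmatched.append(int(i))
            continue
        d2 = dist[key][sub_row_in_group[key][int(i)], free]
        best = d2.min()
        tied = cand[d2 == best]
        if tied.size > 1:
            # lowest (row, col) wins
            j = tied[np.lexsort((ctx.pool_rc[tied, 1], ctx.pool_rc[tied, 0]))[0]]
        else:
            j = tied[0]
        used[j] = True
        pairs.append((int(i), int(j)))

    pairs_arr = np.array(sorted(pairs), dtype=int).reshape(-1, 2)
    xp = ctx.xp[sub_idx]
    xc = ctx.xc
    smds: dict[str, float] = {}
    accepted = True
    reason = None
    if len(pairs_arr):
        pi, ci = pairs_arr[:, 0], pairs_arr[:, 1]
        for k, name in enumerate(CONTINUOUS_COVARIATES):
            val = smd(xc[ci, k], xp[pi, k]) if len(pi) >= 2 else float("nan")
            smds[name] = val
            if np.isnan(val):
                accepted = False
                reason = f"SMD undefined for {name}"
            elif abs(val) > smd_threshold:
                accepted = False
                reason = f"|SMD| > {smd_threshold} for {name}"
    else:
        accepted = False
        reason = "no pairs matched"
    return MatchedSet(
        iteration=iteration,
        pairs=pairs_arr,
        unmatched=np.array(sorted(unmatched), dtype=int),
        smds=smds,
        accepted=accepted,
        rejection_reason=reason,
    )


def greedy_match(
    project_units: pd.DataFrame,
    pool_units: pd.DataFrame,
    seed: int = 0,
    iteration: int = 0,
    smd_threshold: float = 0.25,
) -> MatchedSet:
    """Greedy 1:1 Mahalanobis matching without replacement.

    Project units are processed in a seeded random order; each is paired with
    the unused pool unit of identical categorical covariates that minimises
    the Mahalanobis distance over the continuous covariates (metric estimated
    from the union of the given project units and the pool).  Exact distance
    ties break to the lowest (row, col).  Units with no exact-categorical
    candidate left are recorded unmatched.
    """
    if project_units.empty:
        raise ValueError("project sample is empty")
    ctx = MatchingContext(project_units, pool_units)
    return _greedy_from_context(
        ctx, np.arange(len(project_units)), seed, iteration, smd_threshold
    )


def run_pact(
    stack: LandscapeStack,
    project_polygon: Polygon,
    t0: int,
    horizon_end: int,
    config: PactConfig | None = None,
    all_project_polygons: list[Polygon] | None = None,
    seed: int = 0,
    nodata_mask: np.ndarray | None = None,
) -> PactEstimate:
    """Full PACT run: sample, pool, 100 matched iterations, outcome averaging.

    For each accepted iteration and each year from ``t0`` to ``horizon_end``
    the undisturbed proportion of the matched project and control units is
    multiplied by the project area (ha); averaging across iterations yields
    annual project and counterfactual forest-cover series whose divergence
    since t0 is the cumulative avoided deforestation.
    """
    if config is None:
        config = PactConfig()
    if not stack.has_landcover:
        raise ValueError("stack has no land-cover series")
    if horizon_end <= t0 or horizon_end > int(stack.years.max()):
        raise ValueError(
            f"horizon_end {horizon_end} must lie in ({t0}, {int(stack.years.max())}]"
        )

    cover_rasters = epoch_cover_rasters(stack, t0)
    rows, cols = sample_units(project_polygon, stack.grid, density=config.density)
    project_units = unit_table(
        stack, rows, cols, t0, cover_rasters=cover_rasters, nodata_mask=nodata_mask
    )
    pool = candidate_pool(
        stack,
        project_polygon,
        project_units,
        t0,
        all_project_polygons=all_project_polygons,
        min_distance_km=config.min_distance_km,
        max_distance_km=config.max_distance_km,
        tolerances=config.tolerances,
        pool_density=config.pool_density,
        cover_rasters=cover_rasters,
        nodata_mask=nodata_mask,
    )
    log.info("PACT: %d project units, %d pool units", len(project_units), len(pool))

    area_ha = project_polygon.area / 10_000.0
    years = np.arange(t0, horizon_end + 1)
    year_idx = np.array([stack.year_index(int(y)) for y in years])
    und_project = (
        stack.landcover[year_idx][:, project_units["row"], project_units["col"]]
        == LandCover.UNDISTURBED
    )  # (n_years, n_project_units)
    und_pool = (
        stack.landcover[year_idx][:, pool["row"], pool["col"]] == LandCover.UNDISTURBED
    )

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x6F]))
    n_sub = max(1, int(round(config.sample_fraction * len(project_units))))
    ctx = MatchingContext(project_units, pool)
    matched_sets: list[MatchedSet] = []
    proj_series, cf_series, finals = [], [], []
    for it in range(config.iterations):
        sub_idx = rng.choice(len(project_units), size=n_sub, replace=False)
        it_seed = int(rng.integers(2**31))
        ms = _greedy_from_context(
            ctx, sub_idx, seed=it_seed, iteration=it, smd_threshold=config.smd_threshold
        )
        if ms.accepted and ms.n_pairs < config.min_pairs:
            ms.accepted = False
            ms.rejection_reason = f"only {ms.n_pairs} pairs (< {config.min_pairs})"
        matched_sets.append(ms)
        if not ms.accepted:
            continue
        pi = sub_idx[ms.pairs[:, 0]]  # back to full project-unit indices
        ci = ms.pairs[:, 1]
        p_ha = und_project[:, pi].mean(axis=1) * area_ha
        c_ha = und_pool[:, ci].mean(axis=1) * area_ha
        proj_series.append(p_ha)
        cf_series.append(c_ha)
        avoided = (p_ha - p_ha[0]) - (c_ha - c_ha[0])
        finals.append(avoided[-1])

    n_acc = len(proj_series)
    log.info("PACT: %d of %d iterations accepted by the balance gate", n_acc, config.iterations)
    if n_acc == 0:
        report = pd.concat([ms.balance_frame() for ms in matched_sets], ignore_index=True)
        raise AllIterationsRejectedError(
            "all matching iterations failed the balance gate; balance report:\n"
            + report.groupby("covariate")["smd"].describe().to_string()
        )
    project_ha = np.mean(proj_series, axis=0)
    cf_ha = np.mean(cf_series, axis=0)
    avoided_cum = (project_ha - project_ha[0]) - (cf_ha - cf_ha[0])
    return PactEstimate(
        years=years,
        project_ha=project_ha,
        counterfactual_ha=cf_ha,
        avoided_ha_cumulative=avoided_cum,
        n_iterations_accepted=n_acc,
        iteration_final_avoided=np.asarray(finals, dtype=float),
        matched_sets=matched_sets,
    )
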