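"""File formats and run configuration.

Rasters travel as ESRI ASCII grids (.asc): a plain-text, single-band format
with a six-line header (ncols, nrows, xllcorner, yllcorner, cellsize,
NODATA_value) followed by row-major values, top row first.  A landscape
stack is a directory of aligned .asc layers — one per covariate plus
``landcover_<year>.asc`` per year.  Polygons travel as GeoJSON, tables as
UTF-8 CSV with '.' decimals, and run configuration as TOML.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import Polygon, mapping, shape

from .grids import GridSpec, LandscapeStack

__all__ = [
    "NODATA",
    "read_ascii_grid",
    "write_ascii_grid",
    "read_stack",
    "write_stack",
    "read_polygon",
    "write_polygon",
    "read_project_table",
    "RunConfig",
    "provenance_record",
]

log = logging.getLogger(__name__)

NODATA = -9999.0


def write_ascii_grid(path: str | Path, array: np.ndarray, grid: GridSpec, fmt: str = "%.6g") -> None:
    """Write one layer as an ESRI ASCII grid (row 0 of the array is the
    bottom row of the grid, so it is written last)."""
    if array.shape != grid.shape:
        raise ValueError(f"array shape {array.shape} does not match grid {grid.shape}")
    out = np.where(np.isfinite(array.astype(float)), array, NODATA)
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {grid.origin[0]:.6f}\n"
        f"yllcorner {grid.origin[1]:.6f}\n"
        f"cellsize {grid.pixel_size:.6f}\n"
        f"NODATA_value {NODATA:g}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out[::-1], fmt=fmt)


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, GridSpec, np.ndarray]:
    """Read an ESRI ASCII grid; returns (array, grid, nodata_mask)."""
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        data = np.loadtxt(fh)
    grid = GridSpec(
        n_rows=int(header["nrows"]),
        n_cols=int(header["ncols"]),
        pixel_size=header["cellsize"],
        origin=(header["xllcorner"], header["yllcorner"]),
    )
    data = np.atleast_2d(data)[::-1]  # back to row 0 = bottom
    if data.shape != grid.shape:
        raise ValueError(f"{path}: data shape {data.shape} does not match header {grid.shape}")
    mask = data == header.get("nodata_value", NODATA)
    out = data.astype(float)
    out[mask] = np.nan
    return out, grid, mask


_COVARIATE_LAYERS = ("elevation", "slope", "accessibility", "country", "ecoregion")


def write_stack(directory: str | Path, stack: LandscapeStack) -> None:
    """Write every layer of a stack as .asc files in a directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name in _COVARIATE_LAYERS:
        write_ascii_grid(directory / f"{name}.asc", getattr(stack, name), stack.grid)
    for i, year in enumerate(stack.years):
        write_ascii_grid(directory / f"landcover_{int(year)}.asc", stack.landcover[i], stack.grid, fmt="%d")


def read_stack(directory: str | Path) -> tuple[LandscapeStack, np.ndarray]:
    """Read an aligned stack directory; returns (stack, nodata_mask).

    All layers must share grid dimensions, cell size and origin; a mismatch
    raises with the offending layer names listed.  Nodata cells from any
    covariate layer are combined into one mask.
    """
    directory = Path(directory)
    layers: dict[str, np.ndarray] = {}
    grids: dict[str, GridSpec] = {}
    masks = []
    for name in _COVARIATE_LAYERS:
        path = directory / f"{name}.asc"
        if not path.exists():
            raise FileNotFoundError(f"missing layer {path}")
        layers[name], grids[name], mask = read_ascii_grid(path)
        masks.append(mask)
    lc_paths = sorted(directory.glob("landcover_*.asc"))
    years, lc_layers = [], []
    for path in lc_paths:
        arr, g, _ = read_ascii_grid(path)
        grids[path.stem] = g
        years.append(int(path.stem.split("_")[1]))
        lc_layers.append(arr)
    ref_name, ref = next(iter(grids.items()))
    bad = [name for name, g in grids.items() if g != ref]
    if bad:
        raise ValueError(f"grid mismatch: layers {bad} disagree with {ref_name} ({ref})")
    order = np.argsort(years)
    if lc_layers:
        landcover = np.stack([np.nan_to_num(lc_layers[i], nan=0).astype(np.uint8) for i in order])
        years_arr = np.asarray(years)[order]
    else:
        landcover = np.empty((0, 0, 0), dtype=np.uint8)
        years_arr = np.empty(0, dtype=int)
    nodata_mask = np.any(masks, axis=0)
    for name in ("country", "ecoregion"):
        layers[name] = np.nan_to_num(layers[name], nan=-1).astype(np.int16)
    stack = LandscapeStack(
        grid=ref,
        elevation=layers["elevation"],
        slope=np.clip(np.nan_to_num(layers["slope"], nan=0.0), 0, 90),
        accessibility=np.nan_to_num(layers["accessibility"], nan=0.0),
        country=layers["country"],
        ecoregion=layers["ecoregion"],
        landcover=landcover,
        years=years_arr,
    )
    return stack, nodata_mask


def write_polygon(path: str | Path, polygon: Polygon, properties: dict | None = None) -> None:
    feature = {
        "type": "Feature",
        "geometry": mapping(polygon),
        "properties": properties or {},
    }
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": [feature]}, fh)


def read_polygon(path: str | Path) -> Polygon:
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") == "FeatureCollection":
        geom = gj["features"][0]["geometry"]
    elif gj.get("type") == "Feature":
        geom = gj["geometry"]
    else:
        geom = gj
    return shape(geom)


PROJECT_TABLE_COLUMNS = ("project_id", "certified_ha_yr", "study", "qe_estimate_ha_yr", "years")


def read_project_table(path: str | Path) -> list:
    """Read and validate the long-format per-project estimates CSV.

    Required columns: project_id, certified_ha_yr, study, qe_estimate_ha_yr,
    years.  One row per (project, study); duplicates are rejected, as are
    non-numeric estimate cells (reported with their row numbers).  Negative
    estimates are valid (projects that under-performed their controls).
    Returns a list of :class:`pacteval.crediting.ProjectRecord`.
    """
    from .crediting import ProjectRecord, aggregate_qe

    df = pd.read_csv(path)
    missing = [c for c in PROJECT_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    for col in ("certified_ha_yr", "qe_estimate_ha_yr", "years"):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[numeric.isna() & df[col].notna()] + 2  # 1-based incl. header
        if len(bad):
            raise ValueError(f"{path}: non-numeric values in column {col!r} at rows {list(bad)}")
        df[col] = numeric
    dup = df.duplicated(subset=["project_id", "study"], keep=False)
    if dup.any():
        rows = list(df.index[dup] + 2)
        raise ValueError(f"{path}: duplicate (project_id, study) rows at {rows}")
    records = []
    for pid, grp in df.groupby("project_id", sort=False):
        cert = grp["certified_ha_yr"].iloc[0]
        if grp["certified_ha_yr"].nunique() > 1:
            raise ValueError(f"{path}: project {pid} has conflicting certified values")
        rec = ProjectRecord(
            project_id=str(pid),
            certified=float(cert),
            qe_estimates=[(str(s), float(v)) for s, v in zip(grp["study"], grp["qe_estimate_ha_yr"])],
        )
        records.append(aggregate_qe(rec))
    return records


@dataclass
class RunConfig:
    """End-to-end pipeline configuration (TOML round-trippable).

    Every stochastic stage receives a sub-seed derived from ``seed``, so one
    (config, seed) pair pins the whole pipeline byte-for-byte.
    """

    seed: int = 0
    out_dir: str = "pacteval_out"
    verbosity: str = "INFO"
    # scenario
    n_rows: int = 450
    n_cols: int = 450
    pixel_size: float = 100.0
    smoothness: float = 1000.0
    years: tuple[int, int] = (1999, 2021)
    t0: int = 2011
    project_shape: tuple[int, int] = (60, 60)
    siting_bias: float = 0.5
    treatment_multiplier: float = 0.5
    degradation_fraction: float = 0.3
    spatial_noise_sd: float = 0.1
    hazard_intercept_pct: float = 2.0  # mean annual hazard, percent
    n_projects: int = 3
    certified_inflation: float = 4.0  # synthetic certified = truth * inflation
    # matching
    iterations: int = 100
    sample_fraction: float = 0.10
    density: float | None = None
    pool_density: float | None = 0.25
    min_pairs: int = 30
    # statistics
    n_boot: int = 10_000
    alpha: float = 0.05

    def to_toml(self) -> str:
        lines = []
        for key, val in asdict(self).items():
            if val is None:
                continue  # absent key = None (auto)
            if isinstance(val, str):
                lines.append(f'{key} = "{val}"')
            elif isinstance(val, bool):
                lines.append(f"{key} = {str(val).lower()}")
            elif isinstance(val, (tuple, list)):
                lines.append(f"{key} = [{', '.join(str(v) for v in val)}]")
            else:
                lines.append(f"{key} = {val}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        import tomllib

        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        for key in ("years", "project_shape"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_toml())

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def provenance_record(config: RunConfig) -> dict:
    """Machine-readable provenance: config hash, seed, library versions."""
    import scipy
    import shapely

    from . import __version__

    return {
        "config_sha256_16": config.digest(),
        "seed": config.seed,
        "versions": {
            "pacteval": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "shapely": shapely.__version__,
        },
    }
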