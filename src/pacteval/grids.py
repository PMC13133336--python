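"""Grid geometry and the in-memory landscape container.

Everything downstream (sampling, matching, rate measurement) sees the world
through a :class:`LandscapeStack`: static covariate rasters plus an annual
categorical land-cover series on one common planar grid.  The grid lives in a
projected CRS with metre units; areas are pixel counts times the pixel area in
hectares, and no geographic (lat/lon) handling is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

__all__ = ["LandCover", "GridSpec", "LandscapeStack"]


class LandCover(IntEnum):
    """Annual land-cover classes (tropical moist forest change-collection style).

    ``UNDISTURBED`` is the forest class whose loss defines deforestation
    throughout the package.  Once a pixel leaves ``UNDISTURBED`` it never
    returns: short disturbances pass through ``DEGRADED`` into ``REGROWTH``,
    long ones are absorbed by ``DEFORESTED``.
    """

    UNDISTURBED = 1
    DEGRADED = 2
    DEFORESTED = 3
    REGROWTH = 4
    WATER = 5
    OTHER = 6


@dataclass(frozen=True)
class GridSpec:
    """A regular planar raster grid.

    Parameters
    ----------
    n_rows, n_cols
        Grid dimensions; both must be >= 1.
    pixel_size
        Cell edge length in metres (default 30 m, i.e. a 0.09 ha pixel).
    origin
        (x, y) of the grid's lower-left corner in metres.  Row 0 is the
        bottom row; y increases with row index.
    """

    n_rows: int
    n_cols: int
    pixel_size: float = 30.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.n_rows < 1:
            raise ValueError(f"n_rows must be >= 1, got {self.n_rows}")
        if self.n_cols < 1:
            raise ValueError(f"n_cols must be >= 1, got {self.n_cols}")
        if not self.pixel_size > 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def pixel_area(self) -> float:
        """Area of one pixel in hectares (pixel_size**2 / 10_000)."""
        return self.pixel_size**2 / 10_000.0

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) in metres."""
        x0, y0 = self.origin
        return (x0, y0, x0 + self.n_cols * self.pixel_size, y0 + self.n_rows * self.pixel_size)

    def pixel_centers(self, rows: np.ndarray, cols: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """x, y coordinates (metres) of the centres of the given pixels."""
        x0, y0 = self.origin
        x = x0 + (np.asarray(cols, dtype=float) + 0.5) * self.pixel_size
        y = y0 + (np.asarray(rows, dtype=float) + 0.5) * self.pixel_size
        return x, y

    def all_pixel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(rows, cols, x, y) for every pixel, row-major order."""
        rows, cols = np.indices(self.shape)
        rows, cols = rows.ravel(), cols.ravel()
        x, y = self.pixel_centers(rows, cols)
        return rows, cols, x, y

    def point_to_pixel(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Pixel (row, col) containing each point; points may fall off-grid."""
        x0, y0 = self.origin
        col = np.floor((np.asarray(x, dtype=float) - x0) / self.pixel_size).astype(int)
        row = np.floor((np.asarray(y, dtype=float) - y0) / self.pixel_size).astype(int)
        return row, col

    def in_grid(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        return (rows >= 0) & (rows < self.n_rows) & (cols >= 0) & (cols < self.n_cols)


@dataclass
class LandscapeStack:
    """Covariate rasters plus an annual land-cover series on a common grid.

    ``landcover`` has shape ``(len(years), n_rows, n_cols)`` with
    :class:`LandCover` codes; it may be empty (0 years) for a covariate-only
    stack fresh out of the covariate generator.
    """

    grid: GridSpec
    elevation: np.ndarray
    slope: np.ndarray
    accessibility: np.ndarray
    country: np.ndarray
    ecoregion: np.ndarray
    landcover: np.ndarray = field(default_factory=lambda: np.empty((0, 0, 0), dtype=np.uint8))
    years: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        shape = self.grid.shape
        for name in ("elevation", "slope", "accessibility", "country", "ecoregion"):
            layer = getattr(self, name)
            if layer.shape != shape:
                raise ValueError(f"layer {name!r} has shape {layer.shape}, expected {shape}")
        finite_slope = self.slope[np.isfinite(self.slope)]
        if finite_slope.size and (finite_slope.min() < 0 or finite_slope.max() > 90):
            raise ValueError("slope must lie within [0, 90] degrees")
        finite_acc = self.accessibility[np.isfinite(self.accessibility)]
        if finite_acc.size and finite_acc.min() < 0:
            raise ValueError("accessibility must be non-negative")
        self.years = np.asarray(self.years, dtype=int)
        if self.landcover.size or self.years.size:
            if self.landcover.shape != (len(self.years), *shape):
                raise ValueError(
                    f"landcover has shape {self.landcover.shape}, expected {(len(self.years), *shape)}"
                )
            if np.any(np.diff(self.years) <= 0):
                raise ValueError("years must be strictly increasing")

    @property
    def has_landcover(self) -> bool:
        return self.landcover.size > 0

    def year_index(self, year: int) -> int:
        idx = np.flatnonzero(self.years == year)
        if idx.size == 0:
            raise KeyError(f"year {year} not in landcover series {self.years.min()}..{self.years.max()}")
        return int(idx[0])

    def landcover_in(self, year: int) -> np.ndarray:
        """The land-cover layer for one calendar year."""
        return self.landcover[self.year_index(year)]

    def nearest_year(self, when: float) -> int:
        """Year of the layer closest to ``when``; ties resolve to the earlier layer."""
        if not self.has_landcover:
            raise ValueError("stack has no land-cover series")
        dist = np.abs(self.years - when)
        # argmin returns the first (earlier) index on exact ties
        return int(self.years[int(np.argmin(dist))])

    def with_landcover(self, landcover: np.ndarray, years: np.ndarray) -> "LandscapeStack":
        return LandscapeStack(
            grid=self.grid,
            elevation=self.elevation,
            slope=self.slope,
            accessibility=self.accessibility,
            country=self.country,
            ecoregion=self.ecoregion,
            landcover=landcover,
            years=np.asarray(years, dtype=int),
        )
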