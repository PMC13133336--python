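"""Compound annual deforestation rates and annualised avoided deforestation.

Forest areas at two time points are converted into a constant annual
proportional loss rate r via F_t = F_0 (1 - r)^t, the standard compounding
model for deforestation; its inversion r = 1 - (F_t/F_0)^(1/t) makes
certified and remote-sensing measurements taken over different horizons
directly comparable.  Avoided deforestation is expressed either as ha/year
(cumulative hectares divided by horizon) or as a rate difference in %/year.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from .grids import LandCover, LandscapeStack

__all__ = [
    "compound_rate",
    "forest_cover",
    "annualize_avoided",
    "avoided_rate",
    "RateRecord",
    "EvaluationWindow",
]

log = logging.getLogger(__name__)

#: Mean length of the Gregorian year in days, used to convert certified
#: evaluation windows reported as day counts into real-valued years.
DAYS_PER_YEAR = 365.25


def compound_rate(f0: float, ft: float, t: float) -> float:
    """Annual proportional deforestation rate from start/end forest areas.

    Solves ``ft = f0 * (1 - r)**t`` for r.  Negative r (net forest gain) is
    permitted and logged; ``ft = 0`` returns r = 1 with a total-loss warning.

    Parameters
    ----------
    f0 : hectares of undisturbed forest at the start (> 0).
    ft : hectares at the end (>= 0).
    t : elapsed years (> 0); may be fractional.
    """
    if not f0 > 0:
        raise ValueError(f"F0 must be > 0, got {f0}")
    if ft < 0:
        raise ValueError(f"Ft must be >= 0, got {ft}")
    if not t > 0:
        raise ValueError(f"t must be > 0, got {t}")
    if ft == 0:
        log.warning("total loss: Ft = 0, returning r = 1")
        return 1.0
    r = 1.0 - (ft / f0) ** (1.0 / t)
    if r < 0:
        log.info("negative deforestation rate %.4g (net forest gain)", r)
    return float(r)


def forest_cover(
    stack: LandscapeStack, polygon: Polygon, when: float, forest_class: LandCover = LandCover.UNDISTURBED
) -> float:
    """Forest area (ha) inside a polygon at the yearly layer closest to a date.

    The layer nearest to ``when`` is used (exact ties resolve to the earlier
    layer); the result is the forest-class proportion among polygon pixels
    multiplied by the polygon area in hectares.
    """
    from .landscape import rasterize_polygon

    mask = rasterize_polygon(polygon, stack.grid)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("polygon does not overlap the raster grid")
    year = stack.nearest_year(when)
    layer = stack.landcover_in(year)
    prop = float((layer[mask] == forest_class).mean())
    return prop * polygon.area / 10_000.0


# Backwards-friendly alias: the operation is defined at the project start.
forest_at_start = forest_cover


def annualize_avoided(cumulative_ha: float, n_years: float) -> float:
    """Cumulative avoided deforestation (ha) divided by the horizon in years.

    Negative values are meaningful: they mark projects that lost more forest
    than their quasi-experimental controls.
    """
    if not n_years > 0:
        raise ValueError(f"n_years must be > 0, got {n_years}")
    return float(cumulative_ha) / float(n_years)


def avoided_rate(r_counterfactual: float, r_project: float) -> float:
    """Avoided deforestation as a rate difference in %/year.

    Positive when the counterfactual loses forest faster than the project;
    negative marks under-performance.
    """
    if not (np.isfinite(r_counterfactual) and np.isfinite(r_project)):
        raise ValueError("both rates must be finite")
    return (r_counterfactual - r_project) * 100.0


@dataclass
class RateRecord:
    """One area's compound-rate bookkeeping with the Eq.-style round trip.

    ``source`` distinguishes certified (project-document) measurements from
    annual-change-collection (ACC) remote-sensing measurements.
    """

    project_id: str
    f0_ha: float
    ft_ha: float
    t_years: float
    source: str = "ACC"

    def __post_init__(self) -> None:
        if not self.f0_ha > 0:
            raise ValueError(f"F0 must be > 0, got {self.f0_ha}")
        if self.ft_ha < 0:
            raise ValueError(f"Ft must be >= 0, got {self.ft_ha}")
        if not self.t_years > 0:
            raise ValueError(f"t must be > 0, got {self.t_years}")

    @property
    def rate(self) -> float:
        return compound_rate(self.f0_ha, self.ft_ha, self.t_years)

    @property
    def total_loss(self) -> bool:
        return self.ft_ha == 0

    @property
    def net_gain(self) -> bool:
        return self.ft_ha > self.f0_ha


@dataclass(frozen=True)
class EvaluationWindow:
    """Evaluation period with the source-appropriate year count.

    Certified records measure t as the real-valued day count / 365.25;
    ACC records use the integer number of whole years between annual layers.
    """

    start: date
    end: date

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"end {self.end} must be after start {self.start}")

    @property
    def t_certified(self) -> float:
        return (self.end - self.start).days / DAYS_PER_YEAR

    @property
    def t_acc(self) -> int:
        return self.end.year - self.start.year


def rates_table(records: list[RateRecord]) -> pd.DataFrame:
    """Tabulate rate records (CSV-ready: project_id, F0, Ft, t, r, source)."""
    return pd.DataFrame(
        {
            "project_id": [r.project_id for r in records],
            "F0_ha": [r.f0_ha for r in records],
            "Ft_ha": [r.ft_ha for r in records],
            "t_years": [r.t_years for r in records],
            "r": [r.rate for r in records],
            "source": [r.source for r in records],
        }
    )
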