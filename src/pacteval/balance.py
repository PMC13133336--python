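"""Covariate-balance diagnostics and paired rate comparisons.

Two uses of the same standardised-mean-difference machinery:

* per project, compare a certified *reference area* or a quasi-experimental
  *control set* against the project's own units, covariate by covariate —
  values beyond [-0.25, 0.25] indicate a project-level imbalance.  The
  comparison side takes the "control" role, so a negative accessibility SMD
  means the comparison area is *more* accessible (shorter travel time), the
  direction associated with greater deforestation pressure;
* across projects, test whether the per-covariate SMD distributions differ
  from zero with two-sided one-sample t-tests (no multiplicity adjustment).

Paired deforestation-rate comparisons between measurement sources delegate
to the Wilcoxon signed-rank machinery of :mod:`pacteval.crediting`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .crediting import WilcoxonResult, wilcoxon_signed_rank
from .matching import smd

__all__ = [
    "BALANCE_COVARIATES",
    "RateComparison",
    "balance_report",
    "across_project_tests",
    "rate_discrepancy_test",
    "reference_vs_control_rates",
]

log = logging.getLogger(__name__)

#: Covariates reported in a balance diagnosis; the deforestation covariates
#: at t-5/t-10 are proportional deforested-class cover (change over the
#: preceding 5-year window is derivable from adjacent epochs).
BALANCE_COVARIATES = (
    "elevation",
    "slope",
    "accessibility",
    "prop_undisturbed_t0",
    "prop_undisturbed_t5",
    "prop_undisturbed_t10",
    "prop_deforested_t5",
    "prop_deforested_t10",
)


@dataclass(frozen=True)
class RateComparison:
    """Medians of two paired rate vectors plus the one-tailed Wilcoxon test."""

    median_a: float
    median_b: float
    median_difference: float
    ratio_of_medians: float
    test: WilcoxonResult | None


def balance_report(
    project_units: pd.DataFrame,
    comparison_units: pd.DataFrame,
    area_kind: str = "control",
    project_id: str = "",
    covariates: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Per-covariate SMD of a comparison area against the project.

    Every covariate present in both unit tables yields exactly one row with
    its SMD; covariates missing from either side (e.g. historic epochs
    unavailable for a digitised reference area) or with undefined SMDs are
    flagged rather than silently dropped.

    Returns a frame with columns project_id, area_kind, covariate, smd, flag.
    """
    if len(project_units) < 2 or len(comparison_units) < 2:
        raise ValueError("need at least 2 units on each side")
    if covariates is None:
        covariates = BALANCE_COVARIATES
    rows = []
    for name in covariates:
        if name not in project_units.columns or name not in comparison_units.columns:
            rows.append((project_id, area_kind, name, float("nan"), "unavailable"))
            continue
        val = smd(comparison_units[name].to_numpy(float), project_units[name].to_numpy(float))
        flag = "undefined" if np.isnan(val) else ("outside_band" if abs(val) > 0.25 else "ok")
        rows.append((project_id, area_kind, name, val, flag))
    return pd.DataFrame(rows, columns=["project_id", "area_kind", "covariate", "smd", "flag"])


def across_project_tests(reports: pd.DataFrame) -> pd.DataFrame:
    """Two-sided one-sample t-tests of per-covariate SMDs against zero.

    ``reports`` concatenates per-project balance reports.  Returns one row
    per covariate: n, median SMD, t, df, p.  Zero-variance SMD sets are
    flagged with undefined statistics.  No multiple-testing adjustment.
    """
    out = []
    for name, grp in reports.groupby("covariate", sort=False):
        vals = grp["smd"].to_numpy(float)
        vals = vals[np.isfinite(vals)]
        n = vals.size
        if n < 2:
            out.append((name, n, float(np.median(vals)) if n else float("nan"),
                        float("nan"), n - 1, float("nan"), "too_few"))
            continue
        if np.all(vals == vals[0]):
            out.append((name, n, float(np.median(vals)), float("nan"), n - 1,
                        float("nan"), "zero_variance"))
            continue
        t, p = stats.ttest_1samp(vals, 0.0)
        out.append((name, n, float(np.median(vals)), float(t), n - 1, float(p), "ok"))
    return pd.DataFrame(out, columns=["covariate", "n", "median_smd", "t", "df", "p", "flag"])


def rate_discrepancy_test(
    rates_a: np.ndarray, rates_b: np.ndarray, alternative: str = "greater"
) -> RateComparison:
    """Paired comparison of deforestation rates from two measurement sources.

    Reports the medians of both vectors, the median pairwise difference
    (a - b), and the one-tailed Wilcoxon signed-rank test on the differences.
    With identical vectors the test is undefined and returned as None.
    """
    a = np.asarray(rates_a, dtype=float)
    b = np.asarray(rates_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("paired vectors must have equal length >= 2")
    d = a - b
    try:
        test = wilcoxon_signed_rank(d, alternative=alternative)
    except ValueError:
        log.info("all paired differences are zero; signed-rank test undefined")
        test = None
    med_b = float(np.median(b))
    return RateComparison(
        median_a=float(np.median(a)),
        median_b=med_b,
        median_difference=float(np.median(d)),
        ratio_of_medians=float(np.median(a)) / med_b if med_b != 0 else float("nan"),
        test=test,
    )


def reference_vs_control_rates(
    reference_rates: np.ndarray, control_rates: np.ndarray
) -> RateComparison:
    """Were certified reference areas losing forest faster than QE controls?

    Reference rates are measured over each project's reference period,
    control rates over the project evaluation period; pairs are by project.
    One-tailed alternative: reference > control.
    """
    return rate_discrepancy_test(reference_rates, control_rates, alternative="greater")
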