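"""Over-crediting statistics: per-project aggregation, ratios, paired tests.

A project's certified avoided deforestation (ha/yr, from its monitoring
documents) is compared against the mean of its quasi-experimental estimates.
The over-crediting ratio is certified / mean-QE; the portfolio is summarised
by the mean ratio across projects (positive-mean, credit-issuing projects
only) and the global ratio of summed certified over summed mean-QE avoided
deforestation (negative means included), each with a 10,000-draw project
bootstrap percentile confidence interval.  Systematic over-crediting is
tested with a one-tailed paired Wilcoxon signed-rank test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ProjectRecord",
    "OvercreditingSummary",
    "aggregate_qe",
    "overcrediting_ratio",
    "portfolio_ratios",
    "wilcoxon_signed_rank",
    "significance_summary",
]

log = logging.getLogger(__name__)


@dataclass
class ProjectRecord:
    """Per-project certified estimate plus its quasi-experimental estimates.

    All avoided-deforestation quantities are annualised hectares per year.
    Derived statistics are filled in by :func:`aggregate_qe`; the 95%
    confidence interval is a t-interval with n-1 degrees of freedom and is
    only defined for projects with at least two estimates.
    """

    project_id: str
    certified: float
    qe_estimates: list[tuple[str, float]]  # (study label, ha/yr)
    mean_qe: float = float("nan")
    sd: float = float("nan")
    cv: float = float("nan")
    se: float = float("nan")
    ci95: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not self.qe_estimates:
            raise ValueError(f"project {self.project_id}: needs at least one QE estimate")

    @property
    def n_estimates(self) -> int:
        return len(self.qe_estimates)

    @property
    def has_ci(self) -> bool:
        return self.ci95 is not None


def aggregate_qe(record: ProjectRecord) -> ProjectRecord:
    """Fill mean, sd, cv, se and the 95% t-interval across available studies.

    A single estimate is taken to be the mean; sd, se and the interval stay
    undefined.  Identical estimates give a degenerate interval at the mean.
    """
    values = np.array([v for _, v in record.qe_estimates], dtype=float)
    n = values.size
    record.mean_qe = float(values.mean())
    if n >= 2:
        record.sd = float(values.std(ddof=1))
        record.cv = record.sd / record.mean_qe if record.mean_qe != 0 else float("nan")
        record.se = record.sd / np.sqrt(n)
        tcrit = float(stats.t.ppf(0.975, n - 1))
        record.ci95 = (record.mean_qe - tcrit * record.se, record.mean_qe + tcrit * record.se)
    return record


def overcrediting_ratio(certified: float, mean_qe: float) -> float:
    """Certified avoided deforestation over the mean QE estimate.

    Undefined (NaN) when the mean QE estimate is non-positive — the project
    lost more forest than its controls — or when no credits were issued.
    """
    if certified <= 0 or mean_qe <= 0:
        return float("nan")
    return certified / mean_qe


@dataclass
class OvercreditingSummary:
    """Portfolio over-crediting point estimates, bootstrap CIs and counts."""

    mean_ratio: float
    mean_ratio_ci: tuple[float, float]
    global_ratio: float
    global_ratio_ci: tuple[float, float]
    per_project: pd.DataFrame
    n_reduced: int
    n_significant_reduction: int
    n_significant_overcredit: int
    n_with_ci: int
    n_boot: int
    n_nonfinite_draws: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "mean_ratio": self.mean_ratio,
            "mean_ratio_ci": list(self.mean_ratio_ci),
            "global_ratio": self.global_ratio,
            "global_ratio_ci": list(self.global_ratio_ci),
            "n_reduced": self.n_reduced,
            "n_significant_reduction": self.n_significant_reduction,
            "n_significant_overcredit": self.n_significant_overcredit,
            "n_with_ci": self.n_with_ci,
            "n_boot": self.n_boot,
            "n_nonfinite_draws": self.n_nonfinite_draws,
        }


def _mean_ratio(certified: np.ndarray, mean_qe: np.ndarray) -> float:
    ok = (certified > 0) & (mean_qe > 0)
    if not ok.any():
        return float("nan")
    return float((certified[ok] / mean_qe[ok]).mean())


def _global_ratio(certified: np.ndarray, mean_qe: np.ndarray) -> float:
    denom = mean_qe.sum()
    if denom <= 0:
        return float("nan")
    return float(certified.sum() / denom)


def _percentile_ci(draws: np.ndarray) -> tuple[tuple[float, float], int]:
    finite = draws[np.isfinite(draws)]
    n_bad = int(draws.size - finite.size)
    if finite.size == 0:
        return (float("nan"), float("nan")), n_bad
    lo, hi = np.quantile(finite, [0.025, 0.975])
    return (float(lo), float(hi)), n_bad


def portfolio_ratios(
    records: list[ProjectRecord], n_boot: int = 10_000, seed: int = 0
) -> OvercreditingSummary:
    """Portfolio over-crediting summary with bootstrap confidence intervals.

    Projects are resampled with replacement ``n_boot`` times; the 2.5 and
    97.5 percentiles of the finite draws form the intervals.  Resamples whose
    summed mean-QE estimate is non-positive give non-finite global-ratio
    draws; these are excluded from the percentiles and counted.
    """
    if len(records) < 2:
        raise ValueError("need at least 2 project records")
    records = [aggregate_qe(r) if np.isnan(r.mean_qe) else r for r in records]
    certified = np.array([r.certified for r in records], dtype=float)
    mean_qe = np.array([r.mean_qe for r in records], dtype=float)

    mean_pt = _mean_ratio(certified, mean_qe)
    global_pt = _global_ratio(certified, mean_qe)
    if np.isnan(global_pt):
        log.warning("summed mean QE estimate is non-positive; global ratio undefined")

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x7A]))
    idx = rng.integers(0, len(records), size=(n_boot, len(records)))
    mean_draws = np.array([_mean_ratio(certified[i], mean_qe[i]) for i in idx])
    global_draws = np.array([_global_ratio(certified[i], mean_qe[i]) for i in idx])
    mean_ci, bad_mean = _percentile_ci(mean_draws)
    global_ci, bad_global = _percentile_ci(global_draws)
    if bad_mean or bad_global:
        log.info(
            "bootstrap: %d mean-ratio and %d global-ratio draws were non-finite",
            bad_mean, bad_global,
        )

    counts = significance_summary(records)
    per_project = pd.DataFrame(
        {
            "project_id": [r.project_id for r in records],
            "certified_ha_yr": certified,
            "mean_qe_ha_yr": mean_qe,
            "n_estimates": [r.n_estimates for r in records],
            "ratio": [overcrediting_ratio(c, m) for c, m in zip(certified, mean_qe)],
        }
    )
    return OvercreditingSummary(
        mean_ratio=mean_pt,
        mean_ratio_ci=mean_ci,
        global_ratio=global_pt,
        global_ratio_ci=global_ci,
        per_project=per_project,
        n_reduced=counts["n_reduced"],
        n_significant_reduction=counts["n_significant_reduction"],
        n_significant_overcredit=counts["n_significant_overcredit"],
        n_with_ci=counts["n_with_ci"],
        n_boot=n_boot,
        n_nonfinite_draws={"mean_ratio": bad_mean, "global_ratio": bad_global},
    )


def significance_summary(records: list[ProjectRecord]) -> dict[str, int]:
    """Project counts: reductions, significant reductions, significant over-crediting.

    A project counts as a reduction when its mean QE estimate is positive; as
    a significant reduction when the lower 95% bound exceeds zero; and as
    significantly over-credited when the upper bound falls below the
    certified estimate.  CI-based counts cover only projects with calculable
    intervals (two or more estimates).
    """
    records = [aggregate_qe(r) if np.isnan(r.mean_qe) else r for r in records]
    with_ci = [r for r in records if r.has_ci]
    return {
        "n_reduced": sum(1 for r in records if r.mean_qe > 0),
        "n_significant_reduction": sum(1 for r in with_ci if r.ci95[0] > 0),
        "n_significant_overcredit": sum(1 for r in with_ci if r.ci95[1] < r.certified),
        "n_with_ci": len(with_ci),
    }


# --- Wilcoxon signed-rank -------------------------------------------------

def _exact_wplus_sf_cdf(n: int, v: float) -> tuple[float, float]:
    """P(W+ >= v) and P(W+ <= v) under the exact null for ranks 1..n."""
    # distribution of sums of random subsets of {1..n} via polynomial product
    max_sum = n * (n + 1) // 2
    counts = np.zeros(max_sum + 1)
    counts[0] = 1.0
    for r in range(1, n + 1):
        counts[r:] += counts[:-r].copy()
    counts /= counts.sum()
    sums = np.arange(max_sum + 1)
    return float(counts[sums >= v].sum()), float(counts[sums <= v].sum())


@dataclass(frozen=True)
class WilcoxonResult:
    V: float
    p: float
    n: int
    method: str

    def __iter__(self):
        return iter((self.V, self.p))


def wilcoxon_signed_rank(
    differences: np.ndarray, alternative: str = "greater"
) -> WilcoxonResult:
    """Paired Wilcoxon signed-rank test on a vector of differences.

    V is the sum of the ranks of positive differences after mid-ranking the
    absolute values; zero differences are dropped.  The p-value is exact (by
    enumeration of the null distribution) for n <= 25 without ties, and a
    tie-corrected normal approximation otherwise.

    ``alternative='greater'`` tests whether differences are systematically
    positive.  Raises if every difference is zero (test undefined).
    """
    if alternative not in ("greater", "less", "two-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    d = np.asarray(differences, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all differences are zero: signed-rank test undefined")
    absd = np.abs(d)
    ranks = stats.rankdata(absd)  # mid-ranks on ties
    v = float(ranks[d > 0].sum())

    _, tie_counts = np.unique(absd, return_counts=True)
    has_ties = bool((tie_counts > 1).any())
    if n <= 25 and not has_ties:
        sf, cdf = _exact_wplus_sf_cdf(n, v)
        method = "exact"
    else:
        mu = n * (n + 1) / 4.0
        sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - (tie_counts**3 - tie_counts).sum() / 48.0
        if sigma2 <= 0:
            # all |d| identical and n tiny; the statistic carries no information
            sf = cdf = 1.0
        else:
            z = (v - mu) / np.sqrt(sigma2)
            sf, cdf = float(stats.norm.sf(z)), float(stats.norm.cdf(z))
        method = "normal-tie-corrected"

    if alternative == "greater":
        p = sf
    elif alternative == "less":
        p = cdf
    else:
        p = min(1.0, 2.0 * min(sf, cdf))
    return WilcoxonResult(V=v, p=float(p), n=n, method=method)
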