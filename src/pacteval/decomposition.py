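"""Substitution decomposition of over-crediting mechanisms.

For each project with complete data, five avoided-deforestation rates (in
%/yr) are formed by swapping one ingredient at a time between the
quasi-experimental (ACC-measured, matched-control) assessment and the
certified assessment:

    A = (r_control_acc   - r_project_acc ) * 100   pure quasi-experimental
    B = (r_control_acc   - r_project_cert) * 100   certified project layer
    C = (r_reference_acc - r_project_cert) * 100   certified reference area
    D = (k * r_reference_acc - r_project_cert) * 100   bespoke-corrected reference
    E = (r_baseline_cert - r_project_cert) * 100   pure certified

where k is the correction coefficient — the median ratio of certified to
ACC-measured project-area rates — standing in for unreported bespoke
remote-sensing measurements in reference areas.

Attribution shares are ratios of differences of the *medians* of these
combinations: the project-layer share is (median B - median A) over the gap
(median E - median A), the reference-area share is (median C - median B)
over the gap, and the ex ante modelling share is (median E - median D) over
the gap.  The shares need not sum to 100%: the bespoke-correction overlap is
reported, not hidden.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .crediting import WilcoxonResult, wilcoxon_signed_rank

__all__ = [
    "RATE_COLUMNS",
    "AttributionShares",
    "correction_coefficient",
    "build_ledger",
    "ledger_summary",
    "attribute",
    "paired_certified_vs_qe_test",
]

log = logging.getLogger(__name__)

RATE_COLUMNS = (
    "r_project_acc",
    "r_project_cert",
    "r_control_acc",
    "r_reference_acc",
    "r_baseline_cert",
)
COMBINATIONS = ("A", "B", "C", "D", "E")


def correction_coefficient(certified_rates: np.ndarray, acc_rates: np.ndarray) -> float:
    """Median ratio of certified to ACC-measured project-area rates.

    Pairs with a zero ACC rate are excluded with a warning (ratio undefined).
    """
    cert = np.asarray(certified_rates, dtype=float)
    acc = np.asarray(acc_rates, dtype=float)
    if cert.shape != acc.shape or cert.size < 1:
        raise ValueError("paired rate vectors must have equal length >= 1")
    ok = acc != 0
    if not ok.all():
        log.warning("excluding %d pairs with zero ACC rate", int((~ok).sum()))
    if not ok.any():
        raise ValueError("no pairs with non-zero ACC rate")
    return float(np.median(cert[ok] / acc[ok]))


def build_ledger(rates: pd.DataFrame, k: float | None = None) -> pd.DataFrame:
    """Per-project combination rates A..E in %/yr.

    ``rates`` must contain the five per-project rate columns (annual
    proportional rates, not percentages).  If ``k`` is not given it is
    computed from the table's own certified and ACC project rates; the same
    k applies to every project.
    """
    missing = [c for c in RATE_COLUMNS if c not in rates.columns]
    if missing:
        raise ValueError(f"rate table is missing columns: {missing}")
    if k is None:
        k = correction_coefficient(
            rates["r_project_cert"].to_numpy(), rates["r_project_acc"].to_numpy()
        )
    out = rates.copy()
    out["A"] = (out["r_control_acc"] - out["r_project_acc"]) * 100.0
    out["B"] = (out["r_control_acc"] - out["r_project_cert"]) * 100.0
    out["C"] = (out["r_reference_acc"] - out["r_project_cert"]) * 100.0
    out["D"] = (k * out["r_reference_acc"] - out["r_project_cert"]) * 100.0
    out["E"] = (out["r_baseline_cert"] - out["r_project_cert"]) * 100.0
    out.attrs["k"] = float(k)
    return out


def ledger_summary(ledger: pd.DataFrame) -> pd.DataFrame:
    """Median and interquartile range of each combination across projects."""
    rows = []
    for c in COMBINATIONS:
        v = ledger[c].to_numpy(float)
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        rows.append((c, med, q1, q3))
    return pd.DataFrame(rows, columns=["combination", "median", "q1", "q3"])


@dataclass(frozen=True)
class AttributionShares:
    """Over-crediting attribution, as percentages of the median gap E - A."""

    gap: float
    share_project_layer: float
    share_reference_area: float
    share_ex_ante: float

    def to_dict(self) -> dict:
        return {
            "gap_pct_per_year": self.gap,
            "share_project_layer_pct": self.share_project_layer,
            "share_reference_area_pct": self.share_reference_area,
            "share_ex_ante_pct": self.share_ex_ante,
        }


def attribute(
    median_a: float, median_b: float, median_c: float, median_d: float, median_e: float
) -> AttributionShares:
    """Attribution shares from the five combination medians (%/yr).

    The gap is median(E) - median(A), the total over-crediting to explain.
    Raises when the gap is not positive (nothing to decompose).
    """
    gap = median_e - median_a
    if gap <= 0:
        raise ValueError(f"gap = median(E) - median(A) = {gap:.4g} is not positive; "
                         "shares undefined (no over-crediting to decompose)")
    return AttributionShares(
        gap=float(gap),
        share_project_layer=float((median_b - median_a) / gap * 100.0),
        share_reference_area=float((median_c - median_b) / gap * 100.0),
        share_ex_ante=float((median_e - median_d) / gap * 100.0),
    )


def attribute_from_ledger(ledger: pd.DataFrame) -> AttributionShares:
    meds = [float(ledger[c].median()) for c in COMBINATIONS]
    return attribute(*meds)


def paired_certified_vs_qe_test(
    e_column: np.ndarray, a_column: np.ndarray
) -> tuple[float, float, WilcoxonResult]:
    """Medians of the pure-certified and pure-QE combinations plus the
    one-tailed Wilcoxon signed-rank test on their paired differences."""
    e = np.asarray(e_column, dtype=float)
    a = np.asarray(a_column, dtype=float)
    if e.shape != a.shape or e.size < 2:
        raise ValueError("paired columns must have equal length >= 2")
    test = wilcoxon_signed_rank(e - a, alternative="greater")
    return float(np.median(e)), float(np.median(a)), test
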