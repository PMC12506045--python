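"""Incremental cost-effectiveness analysis and reporting.

Implements the standard decision-analytic summary measures: the incremental
cost-effectiveness ratio ICER = ΔC/ΔE between a strategy and the
no-intervention reference, the net monetary benefit NMB(λ) = λ·ΔE − ΔC at a
willingness-to-pay λ, dominance handling, and classification against the
1×/3× GDP-per-capita thresholds.  Comparisons are pairwise against the
reference strategy, matching the reporting layout of the source analysis.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "StrategyResult",
    "CEStatus",
    "CEResult",
    "ThresholdClass",
    "incremental",
    "nmb",
    "compare_to_threshold",
    "make_report",
]


@dataclass(frozen=True)
class StrategyResult:
    """Discounted lifetime totals for one strategy.

    ``cbhi_cost`` is the programme/intervention cost (tree phase plus any
    rescreening events); ``treatment_cost`` is the health-state cost accrued
    in the Markov phase.  ``total_cost`` must equal their sum.
    """

    strategy: str
    total_cost: float
    total_qaly: float
    cbhi_cost: float
    treatment_cost: float

    def __post_init__(self):
        if abs(self.total_cost - (self.cbhi_cost + self.treatment_cost)) > 1e-6:
            raise ValueError(
                "total_cost must equal cbhi_cost + treatment_cost "
                f"({self.total_cost} vs {self.cbhi_cost + self.treatment_cost})"
            )
        if self.total_qaly < 0:
            raise ValueError("total_qaly must be nonnegative")


class CEStatus(str, enum.Enum):
    ICER = "icer"
    DOMINANT = "dominant"      # cheaper and at least as effective
    DOMINATED = "dominated"    # costlier and at most as effective
    ZERO_EFFECT = "zero_effect"


@dataclass(frozen=True)
class CEResult:
    """Pairwise incremental result of one strategy against the reference."""

    strategy: str
    reference: str
    delta_cost: float
    delta_qaly: float
    status: CEStatus
    icer: float | None

    def nmb(self, wtp: float) -> float:
        return nmb(self, wtp)


_EFFECT_EPS = 1e-12


def incremental(ref: StrategyResult, alt: StrategyResult) -> CEResult:
    """ΔC, ΔE and the ICER (or a dominance flag) of ``alt`` vs ``ref``."""
    dc = alt.total_cost - ref.total_cost
    de = alt.total_qaly - ref.total_qaly
    if abs(de) < _EFFECT_EPS:
        # No measurable health effect: the ratio is undefined whatever ΔC is.
        status, icer = CEStatus.ZERO_EFFECT, None
    elif dc <= 0 and de >= 0:
        status, icer = CEStatus.DOMINANT, None
    elif dc >= 0 and de <= 0:
        status, icer = CEStatus.DOMINATED, None
    else:
        status, icer = CEStatus.ICER, dc / de
    return CEResult(alt.strategy, ref.strategy, dc, de, status, icer)


def nmb(ce: CEResult, wtp: float) -> float:
    """Net monetary benefit λ·ΔE − ΔC at willingness-to-pay λ >= 0."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be nonnegative")
    return wtp * ce.delta_qaly - ce.delta_cost


class ThresholdClass(str, enum.Enum):
    COST_SAVING = "cost_saving"
    CE_AT_1GDP = "ce_at_1gdp"
    CE_AT_3GDP = "ce_at_3gdp"
    NOT_CE = "not_ce"


def compare_to_threshold(ce: CEResult, gdp_per_capita: float) -> ThresholdClass:
    """Classify against willingness-to-pay thresholds of 1x and 3x GDP per capita."""
    if ce.status is CEStatus.DOMINANT:
        return ThresholdClass.COST_SAVING
    if ce.status in (CEStatus.DOMINATED, CEStatus.ZERO_EFFECT):
        return ThresholdClass.NOT_CE
    assert ce.icer is not None
    if ce.icer <= gdp_per_capita:
        return ThresholdClass.CE_AT_1GDP
    if ce.icer <= 3.0 * gdp_per_capita:
        return ThresholdClass.CE_AT_3GDP
    return ThresholdClass.NOT_CE


def make_report(results: dict[str, StrategyResult], reference: str) -> pd.DataFrame:
    """Cost-effectiveness table: one column per strategy, rows for programme
    cost, treatment cost, total cost, QALYs, incrementals and the ICER
    versus the reference strategy.  Values unrounded; round at display time.
    """
    ref = results[reference]
    rows = {
        "cbhi_cost": {},
        "treatment_cost": {},
        "total_cost": {},
        "total_qaly": {},
        "incremental_cost": {},
        "incremental_qaly": {},
        "icer": {},
    }
    for name, res in results.items():
        rows["cbhi_cost"][name] = res.cbhi_cost
        rows["treatment_cost"][name] = res.treatment_cost
        rows["total_cost"][name] = res.total_cost
        rows["total_qaly"][name] = res.total_qaly
        if name == reference:
            rows["incremental_cost"][name] = float("nan")
            rows["incremental_qaly"][name] = float("nan")
            rows["icer"][name] = float("nan")
        else:
            ce = incremental(ref, res)
            rows["incremental_cost"][name] = ce.delta_cost
            rows["incremental_qaly"][name] = ce.delta_qaly
            rows["icer"][name] = ce.icer if ce.icer is not None else float("nan")
    return pd.DataFrame(rows).T[list(results)]
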