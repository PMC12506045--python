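"""Scenario analyses: repeated rescreening, uptake/adherence grids and the
knowledge-gain threshold for cost saving.

Three policy questions layered on the base model:

1. **Repeated rescreening** — instead of a single screening round, persons
   still free of diagnosed diabetes are rescreened during the first 10
   years: pre-diabetes, moderate- and (unmanaged) high-risk NGT annually,
   low-risk NGT every third year, and screen-missed (flagged) undiagnosed
   diabetes annually.  Participation per event equals the referral
   follow-up rate (6%).
2. **Uptake / adherence grid** — how low can uptake or referral adherence
   go before a strategy stops being cost-effective at a given
   willingness-to-pay threshold.
3. **Knowledge-gain search** — the smallest education-induced knowledge
   gain at which the education strategy becomes cost-saving outright.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .economics import CEResult, CEStatus, StrategyResult, incremental
from .markov_engine import Compartment, State, StateSpace, accrue_outcomes, run_markov
from .params import LifeTable, ParameterSet
from .screening_tree import Strategy, screen_cohort
from .pipeline import run_strategy

__all__ = [
    "RescreenSchedule",
    "run_repeated",
    "grid_minimum",
    "knowledge_gain_for_cost_saving",
]


@dataclass(frozen=True)
class RescreenSchedule:
    """Who gets rescreened when, and what each event costs.

    ``triennial_cycles`` lists the cycles at which low-risk NGT is
    rescreened within the window.  ``two_step_cascade`` keeps rescreen
    participation and subsequent referral adherence as two multiplicative
    hurdles (participation selects who is screened; screen-positive persons
    must then still follow the referral); collapsing it treats participation
    as already implying follow-up.
    """

    window: int = 10
    participation: float = 0.06
    triennial_cycles: tuple[int, ...] = (3, 6, 9)
    two_step_cascade: bool = True

    def __post_init__(self):
        if self.window < 0:
            raise ValueError("window must be >= 0")
        if not (0.0 <= self.participation <= 1.0):
            raise ValueError("participation must be a probability")

    @classmethod
    def from_parameters(cls, ps: ParameterSet) -> "RescreenSchedule":
        w = int(ps["rescreen_window"])
        return cls(
            window=w,
            participation=ps["rescreen_adherence"],
            triennial_cycles=tuple(c for c in range(3, w + 1, 3)),
        )


def _rescreen_hook(ps: ParameterSet, sched: RescreenSchedule):
    """Build the cycle hook that performs scheduled rescreening events."""
    se = ps["rcbg_sensitivity"]
    adh = ps["referral_adherence"] if sched.two_step_cascade else 1.0
    part = sched.participation
    kit = ps["pc_rcbg_kit"]
    incentives = ps["pc_chw_incentives_yearly"]

    def hook(cycle: int, x: np.ndarray, space: StateSpace):
        if cycle > sched.window or part == 0.0:
            return x, 0.0, 0.0
        annual = cycle <= sched.window
        triennial = cycle in sched.triennial_cycles
        screened = 0.0
        for edu in (False, True):
            eligible: list[Compartment] = []
            if annual:
                eligible += [
                    Compartment(State.PREDIABETES, edu, False),
                    Compartment(State.NGT_MOD, edu, False),
                    Compartment(State.NGT_HIGH, edu, False),
                    Compartment(State.T2D_UNDIAGNOSED, edu, flagged=True),
                ]
            if triennial:
                eligible.append(Compartment(State.NGT_LOW, edu, False))
            for comp in eligible:
                i = space.index[comp]
                mass = x[i] * part
                if mass == 0.0:
                    continue
                screened += mass
                if comp.state is State.T2D_UNDIAGNOSED:
                    # flagged false negatives: detected with prob Se, then
                    # (optionally) the referral hurdle again
                    detected = mass * se * adh
                    x[i] -= detected
                    x[space.index[Compartment(State.T2D_DIAGNOSED, edu, setting="phc")]] += detected
                elif comp.state is State.NGT_HIGH:
                    # high risk: referred regardless of the glucose result
                    managed = mass * adh
                    x[i] -= managed
                    x[space.index[Compartment(State.NGT_HIGH, edu, True)]] += managed
                # other tiers: false positives are referred back; no state change
        cost = 0.0
        if screened > 0.0:
            cost = kit * screened + incentives
        return x, cost, screened

    return hook


def run_repeated(
    ps: ParameterSet,
    sched: RescreenSchedule,
    strategy: Strategy | str,
    lt: LifeTable,
) -> StrategyResult:
    """Lifetime result of a strategy with scheduled rescreening.

    Identical to the one-time strategy except that during cycles
    1..window the scheduled fraction of each eligible compartment is
    rescreened (same test accuracy): detected diabetes moves to
    primary-care treatment, detected high risk enrols in risk management,
    and kit plus yearly worker-incentive costs accrue in the cycles where
    screening actually happens.  A schedule with zero participation (or a
    zero-length window) reproduces the one-time result exactly.
    """
    strategy = Strategy(strategy)
    if strategy is Strategy.REFERENCE:
        raise ValueError("rescreening applies only to active strategies")
    horizon = int(ps["age_cap"]) - int(ps["start_age"])
    if sched.window > horizon:
        raise ValueError(f"window {sched.window} exceeds horizon {horizon}")
    label = strategy.value + "_repeated"
    return run_strategy(ps, lt, strategy, cycle_hook=_rescreen_hook(ps, sched), label=label)


def grid_minimum(
    ps: ParameterSet,
    lt: LifeTable,
    axis: str,
    threshold: float,
    strategy: Strategy | str = Strategy.SCREENING,
    grid: np.ndarray | None = None,
    repeated: bool = False,
) -> tuple[pd.DataFrame, float | None]:
    """ICER of a strategy along an uptake or adherence grid.

    Evaluates the strategy at each grid level (all other parameters at
    base), and returns the table of incrementals plus the smallest level at
    which the strategy is cost-effective at ``threshold`` (cost-saving
    dominance also qualifies), or None if no level qualifies.
    """
    if axis not in ("uptake", "adherence"):
        raise ValueError("axis must be 'uptake' or 'adherence'")
    if grid is None:
        grid = np.round(np.arange(0.05, 1.0001, 0.05), 10)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty grid")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be sorted ascending")
    strategy = Strategy(strategy)

    rows = []
    minimum = None
    for level in grid:
        if axis == "uptake":
            updates = {"uptake": level}
        else:
            updates = {"referral_adherence": level, "rescreen_adherence": level}
        psl = ps.with_values(updates)
        ref = run_strategy(psl, lt, Strategy.REFERENCE)
        if repeated:
            alt = run_repeated(psl, RescreenSchedule.from_parameters(psl), strategy, lt)
        else:
            alt = run_strategy(psl, lt, strategy)
        ce = incremental(ref, alt)
        qualifies = ce.status is CEStatus.DOMINANT or (
            ce.status is CEStatus.ICER and ce.icer is not None and ce.icer <= threshold
        )
        rows.append(
            {
                "level": level,
                "delta_cost": ce.delta_cost,
                "delta_qaly": ce.delta_qaly,
                "icer": ce.icer if ce.icer is not None else float("nan"),
                "status": ce.status.value,
                "cost_effective": qualifies,
            }
        )
        if qualifies and minimum is None:
            minimum = float(level)
    return pd.DataFrame(rows), minimum


def knowledge_gain_for_cost_saving(
    ps: ParameterSet, lt: LifeTable, step: float = 0.1
) -> float | None:
    """Smallest education knowledge gain making the education strategy
    cost-saving against no intervention (ΔC <= 0), scanning 0..scale max in
    ``step``-point increments; None if no gain on the scale suffices."""
    if step <= 0:
        raise ValueError("step must be positive")
    ref = run_strategy(ps, lt, Strategy.REFERENCE)
    max_gain = ps["knowledge_scale_max_gain"]
    for dk in np.arange(0.0, max_gain + step / 2, step):
        dk = float(min(dk, max_gain))
        alt = run_strategy(ps.with_values({"atet_knowledge": dk}), lt, Strategy.SCREENING_EDUCATION)
        if alt.total_cost - ref.total_cost <= 0.0:
            return dk
    return None
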