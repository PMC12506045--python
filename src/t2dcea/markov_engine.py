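"""Lifetime multi-state cohort projection.

The Markov engine extrapolates the decision-tree allocation over the
cohort's remaining lifetime with 1-year cycles.  Eight health states —
three tiers of normal glucose tolerance (low / moderate / high risk),
pre-diabetes, undiagnosed T2D, diagnosed T2D, cardiovascular disease and
death — are crossed with strata that modify costs, utilities or transition
intensities without being disease states themselves:

* ``educated``          — attended health education; incidence of
                          pre-diabetes and T2D is scaled by the education
                          risk multiplier (see :mod:`t2dcea.education`).
* ``prolanis_managed``  — enrolled in primary-care risk management; the same
                          incidence probabilities are scaled by a management
                          relative risk, a yearly management cost accrues,
                          and progression to diabetes is detected at once
                          (diagnosed at primary care rather than lapsing
                          into the undiagnosed state).
* ``diagnosis setting`` — diabetes diagnosed via screening is treated at
                          primary care; diabetes detected late presents at
                          secondary (specialist) care, with different annual
                          cost and utility.
* ``flagged``           — undiagnosed T2D known to the programme as
                          high-risk (a false negative at screening); only
                          relevant under repeated-screening schedules.

Competing risks are composed mortality-first: each live state sends
``qx(age)`` to death (the cardiovascular state adds its case fatality,
``1 − (1 − qx)(1 − cf)``), and the survivors are redistributed by the
age-independent conditional transition matrix.  The undiagnosed state's
cardiovascular risk is elevated by a hazard ratio applied on the
complementary-log scale, ``1 − (1 − p)^HR``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .education import effect_from_parameters, knowledge_to_rr
from .params import LifeTable, ParameterSet
from .screening_tree import Group, TreeOutput

__all__ = [
    "State",
    "Compartment",
    "StateSpace",
    "MarkovTrace",
    "build_state_space",
    "build_transition_matrix",
    "run_markov",
    "accrue_outcomes",
    "map_tree_to_compartments",
    "life_expectancy",
    "gompertz_life_table",
]


class State(str, enum.Enum):
    NGT_LOW = "NGT_LOW"
    NGT_MOD = "NGT_MOD"
    NGT_HIGH = "NGT_HIGH"
    PREDIABETES = "PREDIABETES"
    T2D_UNDIAGNOSED = "T2D_UNDIAGNOSED"
    T2D_DIAGNOSED = "T2D_DIAGNOSED"
    CVD = "CVD"
    DEAD = "DEAD"


_NGT_STATES = (State.NGT_LOW, State.NGT_MOD, State.NGT_HIGH)


@dataclass(frozen=True)
class Compartment:
    """One (state × stratum) cell of the projection.

    ``setting`` is 'phc' or 'secondary' for diagnosed diabetes, None
    elsewhere; ``flagged`` marks programme-known undiagnosed diabetes.
    """

    state: State
    educated: bool = False
    managed: bool = False
    setting: str | None = None
    flagged: bool = False

    def label(self) -> str:
        bits = [self.state.value]
        if self.setting:
            bits.append(self.setting)
        if self.educated:
            bits.append("edu")
        if self.managed:
            bits.append("mgd")
        if self.flagged:
            bits.append("flag")
        return "|".join(bits)


@dataclass
class StateSpace:
    """Ordered compartments with per-compartment annual utility and cost."""

    compartments: list[Compartment]
    utilities: np.ndarray
    costs: np.ndarray
    index: dict[Compartment, int]

    def __len__(self) -> int:
        return len(self.compartments)

    @property
    def dead_index(self) -> int:
        return self.index[Compartment(State.DEAD)]


def build_state_space(ps: ParameterSet) -> StateSpace:
    comps: list[Compartment] = []
    for edu in (False, True):
        for managed in (False, True):
            for st in (*_NGT_STATES, State.PREDIABETES):
                comps.append(Compartment(st, educated=edu, managed=managed))
        for flagged in (False, True):
            comps.append(Compartment(State.T2D_UNDIAGNOSED, educated=edu, flagged=flagged))
        for setting in ("phc", "secondary"):
            comps.append(Compartment(State.T2D_DIAGNOSED, educated=edu, setting=setting))
        comps.append(Compartment(State.CVD, educated=edu))
    comps.append(Compartment(State.DEAD))

    util = np.zeros(len(comps))
    cost = np.zeros(len(comps))
    for i, c in enumerate(comps):
        if c.state in _NGT_STATES:
            util[i] = ps["u_ngt"]
            cost[i] = ps["c_prolanis_highrisk"] if c.managed else 0.0
        elif c.state is State.PREDIABETES:
            util[i] = ps["u_prediabetes"]
            cost[i] = ps["c_prolanis_highrisk"] if c.managed else 0.0
        elif c.state is State.T2D_UNDIAGNOSED:
            util[i] = ps["u_t2d_undiagnosed"]
        elif c.state is State.T2D_DIAGNOSED:
            util[i] = ps["u_t2d_phc"] if c.setting == "phc" else ps["u_t2d_secondary"]
            cost[i] = ps["c_t2d_phc"] if c.setting == "phc" else ps["c_t2d_secondary"]
        elif c.state is State.CVD:
            util[i] = ps["u_cvd"]
            cost[i] = ps["c_cvd"]
    return StateSpace(comps, util, cost, {c: i for i, c in enumerate(comps)})


def _conditional_matrix(ps: ParameterSet, space: StateSpace) -> np.ndarray:
    """Annual transition matrix conditional on surviving the cycle.

    Age-independent: mortality is layered on separately.  Raises if any
    row's outgoing probability mass exceeds 1, naming the compartment.
    """
    k = len(space)
    C = np.zeros((k, k))
    edu_mult = knowledge_to_rr(effect_from_parameters(ps))
    mgmt = ps["rr_prolanis_management"]
    p_cvd = ps["tp_t2d_to_cvd"]
    p_cvd_undiag = 1.0 - (1.0 - p_cvd) ** ps["hr_cvd_undiagnosed"]

    for i, c in enumerate(space.compartments):
        mult = (edu_mult if c.educated else 1.0) * (mgmt if c.managed else 1.0)
        row: dict[int, float] = {}
        if c.state is State.NGT_LOW:
            row[space.index[Compartment(State.NGT_MOD, c.educated, c.managed)]] = ps["tp_ngt_low_to_mod"]
            row[space.index[Compartment(State.PREDIABETES, c.educated, c.managed)]] = ps["tp_ngt_low_to_pre"] * mult
        elif c.state is State.NGT_MOD:
            row[space.index[Compartment(State.NGT_HIGH, c.educated, c.managed)]] = ps["tp_ngt_mod_to_high"]
            row[space.index[Compartment(State.PREDIABETES, c.educated, c.managed)]] = ps["tp_ngt_mod_to_pre"] * mult
        elif c.state is State.NGT_HIGH:
            row[space.index[Compartment(State.PREDIABETES, c.educated, c.managed)]] = ps["tp_ngt_high_to_pre"] * mult
        elif c.state is State.PREDIABETES:
            p = ps["tp_pre_to_t2d"] * mult
            if c.managed:
                # under risk management, incident diabetes is caught at once
                dest = Compartment(State.T2D_DIAGNOSED, c.educated, setting="phc")
            else:
                dest = Compartment(State.T2D_UNDIAGNOSED, c.educated)
            row[space.index[dest]] = p
        elif c.state is State.T2D_UNDIAGNOSED:
            row[space.index[Compartment(State.T2D_DIAGNOSED, c.educated, setting="secondary")]] = ps["tp_undiag_detection"]
            row[space.index[Compartment(State.CVD, c.educated)]] = p_cvd_undiag
        elif c.state is State.T2D_DIAGNOSED:
            row[space.index[Compartment(State.CVD, c.educated)]] = p_cvd
        # CVD and DEAD have no conditional exits.

        out = sum(row.values())
        if out > 1.0 + 1e-12:
            raise ValueError(
                f"outgoing transition mass {out:.6g} > 1 from compartment {c.label()}"
            )
        for v in row.values():
            if v < -1e-15:
                raise ValueError(f"negative transition probability from {c.label()}")
        for j, v in row.items():
            C[i, j] = v
        C[i, i] = 1.0 - out
    return C


def _death_vector(ps: ParameterSet, space: StateSpace, lt: LifeTable, age: int) -> np.ndarray:
    q = lt.q(age)
    cf = ps["tp_cvd_case_fatality"]
    d = np.full(len(space), q)
    for i, c in enumerate(space.compartments):
        if c.state is State.CVD:
            d[i] = 1.0 - (1.0 - q) * (1.0 - cf)
        elif c.state is State.DEAD:
            d[i] = 0.0
    return d


def build_transition_matrix(
    ps: ParameterSet, age: int, lt: LifeTable, space: StateSpace | None = None
) -> np.ndarray:
    """Full row-stochastic annual transition matrix at a given age.

    Mortality first: entry (i, j) for live j is ``(1 − d_i) C_ij`` and the
    death column receives ``d_i``, with ``d_i = 1 − (1 − qx)(1 − cf_i)``.
    """
    space = space or build_state_space(ps)
    C = _conditional_matrix(ps, space)
    d = _death_vector(ps, space, lt, age)
    M = C * (1.0 - d)[:, None]
    M[:, space.dead_index] += d
    M[space.dead_index, :] = 0.0
    M[space.dead_index, space.dead_index] = 1.0
    if np.any(M < -1e-12) or np.any(M > 1.0 + 1e-12):
        bad = np.argwhere((M < -1e-12) | (M > 1 + 1e-12))[0]
        ci, cj = space.compartments[bad[0]], space.compartments[bad[1]]
        raise ValueError(f"transition {ci.label()} -> {cj.label()} outside [0,1]")
    return M


@dataclass
class MarkovTrace:
    """Cycle-by-cycle projection output.

    ``occupancy[t]`` is the compartment vector after cycle ``t`` (row 0 is
    the tree output); per-cycle cost and QALY vectors are undiscounted and
    evaluated on end-of-cycle occupancy (row 0 therefore contributes
    nothing).  ``cbhi_cycle_costs`` carries programme costs incurred during
    the Markov phase (rescreening events); zero for one-time strategies.
    """

    occupancy: np.ndarray
    ages: np.ndarray
    cycle_cost: np.ndarray
    cycle_qaly: np.ndarray
    cbhi_cycle_costs: np.ndarray
    cycle_screened: np.ndarray
    space: StateSpace
    cohort_size: float

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    def check_conservation(self, tol: float = 1e-6) -> None:
        sums = self.occupancy.sum(axis=1)
        if np.max(np.abs(sums - self.cohort_size)) > tol:
            raise AssertionError("occupancy rows do not conserve cohort size")

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(
            self.occupancy, columns=[c.label() for c in self.space.compartments]
        )
        df.insert(0, "age", self.ages)
        df.insert(0, "cycle", np.arange(len(df)))
        df["cost"] = self.cycle_cost
        df["qaly"] = self.cycle_qaly
        return df


def map_tree_to_compartments(tree: TreeOutput, space: StateSpace) -> np.ndarray:
    """Initial occupancy vector from the decision-tree end groups."""
    x = np.zeros(len(space))
    group_state = {
        Group.PREDIABETES: (State.PREDIABETES, False, None),
        Group.NGT_LOW: (State.NGT_LOW, False, None),
        Group.NGT_MOD: (State.NGT_MOD, False, None),
        Group.NGT_HIGH_TREATED: (State.NGT_HIGH, True, None),
        Group.NGT_HIGH_UNTREATED: (State.NGT_HIGH, False, None),
        Group.T2D_DIAGNOSED_PHC: (State.T2D_DIAGNOSED, False, "phc"),
    }
    for (g, stratum), mass in tree.occupancy.items():
        if mass == 0.0:
            continue
        edu = stratum == "educated"
        if g is Group.T2D_UNDIAGNOSED:
            fl = min(tree.flagged_false_negatives.get(stratum, 0.0), mass)
            x[space.index[Compartment(State.T2D_UNDIAGNOSED, edu, flagged=True)]] += fl
            x[space.index[Compartment(State.T2D_UNDIAGNOSED, edu, flagged=False)]] += mass - fl
        else:
            st, managed, setting = group_state[g]
            x[space.index[Compartment(st, edu, managed, setting)]] += mass
    return x


#: hook(cycle, occupancy_vector, space) -> (new_occupancy, cbhi_cost, screened)
CycleHook = Callable[[int, np.ndarray, StateSpace], tuple[np.ndarray, float, float]]


def run_markov(
    tree: TreeOutput,
    ps: ParameterSet,
    lt: LifeTable,
    cycle_hook: CycleHook | None = None,
) -> MarkovTrace:
    """Project the tree output through annual cycles until extinction.

    Cycles run from the start age until the dead compartment holds the whole
    cohort (to within 1e−9 of a person-fraction) or the life-table cap is
    reached.  An optional ``cycle_hook`` (used by the repeated-screening
    scenario) may move mass between compartments at the start of each cycle,
    before that cycle's transition, and report programme costs and persons
    screened for that cycle.
    """
    space = build_state_space(ps)
    x = map_tree_to_compartments(tree, space)
    n = ps["cohort_size"]
    if abs(x.sum() - n) > 1e-6:
        raise ValueError("tree occupancy does not conserve the cohort size")

    start_age = int(ps["start_age"])
    age_cap = int(ps["age_cap"])
    C = _conditional_matrix(ps, space)
    dead = space.dead_index

    occ = [x]
    costs = [0.0]
    qalys = [0.0]
    cbhi = [0.0]
    screened = [0.0]
    ages = [start_age]
    t = 0
    while True:
        age = start_age + t
        if age >= age_cap or occ[-1][dead] >= n * (1.0 - 1e-9):
            break
        t += 1
        xt = occ[-1]
        extra_cost = 0.0
        extra_screened = 0.0
        if cycle_hook is not None:
            xt, extra_cost, extra_screened = cycle_hook(t, xt.copy(), space)
        d = _death_vector(ps, space, lt, age)
        survivors = xt * (1.0 - d)
        xnext = survivors @ C
        xnext[dead] += xt @ d
        occ.append(xnext)
        costs.append(float(xnext @ space.costs))
        qalys.append(float(xnext @ space.utilities))
        cbhi.append(extra_cost)
        screened.append(extra_screened)
        ages.append(start_age + t)

    trace = MarkovTrace(
        occupancy=np.vstack(occ),
        ages=np.array(ages),
        cycle_cost=np.array(costs),
        cycle_qaly=np.array(qalys),
        cbhi_cycle_costs=np.array(cbhi),
        cycle_screened=np.array(screened),
        space=space,
        cohort_size=n,
    )
    trace.check_conservation()
    return trace


def accrue_outcomes(trace: MarkovTrace, ps: ParameterSet, tree_cost: float, strategy: str = ""):
    """Discounted lifetime totals from a trace.

    Costs and QALYs accrued in cycle t are discounted by (1+r)^−t; the tree
    phase (t = 0) is undiscounted.  Programme costs incurred during the
    Markov phase (rescreening) are discounted alongside and reported within
    ``cbhi_cost``.
    """
    from .economics import StrategyResult

    r = ps["discount_rate"]
    t = np.arange(trace.occupancy.shape[0], dtype=float)
    disc = (1.0 + r) ** (-t)
    treatment = float(trace.cycle_cost @ disc)
    qaly = float(trace.cycle_qaly @ disc)
    cbhi = tree_cost + float(trace.cbhi_cycle_costs @ disc)
    return StrategyResult(
        strategy=strategy,
        total_cost=cbhi + treatment,
        total_qaly=qaly,
        cbhi_cost=cbhi,
        treatment_cost=treatment,
    )


def life_expectancy(lt: LifeTable, start_age: int) -> float:
    """Expected remaining years under end-of-cycle counting.

    Sum over t >= 1 of the probability of surviving the first t cycles,
    matching the accrual convention of :func:`run_markov` (a person alive at
    the end of a cycle contributes that full cycle).
    """
    total = 0.0
    surv = 1.0
    age = start_age
    while age <= lt.ages[-1]:
        surv *= 1.0 - lt.q(age)
        total += surv
        if surv == 0.0:
            break
        age += 1
    return total


def gompertz_life_table(
    a: float = 5e-4, b: float = 0.085, start_age: int = 40, age_cap: int = 110
) -> LifeTable:
    """Gompertz mortality ``qx = min(1, a·exp(b·(age − start)))`` with a
    closing age at which death is certain."""
    if a <= 0 or b < 0:
        raise ValueError("require a > 0 and b >= 0")
    ages = tuple(range(start_age, age_cap + 1))
    qx = [min(1.0, float(a * np.exp(b * (age - start_age)))) for age in ages]
    qx[-1] = 1.0
    return LifeTable(ages, tuple(qx))
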