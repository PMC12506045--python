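"""Markov engine: transition composition, accrual identities, oracles."""

import numpy as np
import pytest

from t2dcea.markov_engine import (
    Compartment,
    State,
    accrue_outcomes,
    build_state_space,
    build_transition_matrix,
    gompertz_life_table,
    life_expectancy,
    run_markov,
    MarkovTrace,
)
from t2dcea.params import LifeTable
from t2dcea.screening_tree import Strategy, screen_cohort

ZERO_TRANSITIONS = {
    "tp_ngt_low_to_mod": 0.0, "tp_ngt_mod_to_high": 0.0,
    "tp_ngt_low_to_pre": 0.0, "tp_ngt_mod_to_pre": 0.0,
    "tp_ngt_high_to_pre": 0.0, "tp_pre_to_t2d": 0.0,
    "tp_undiag_detection": 0.0, "tp_t2d_to_cvd": 0.0,
    "tp_cvd_case_fatality": 0.0,
}
UNIT_UTILITIES = {k: 1.0 for k in
                  ("u_ngt", "u_prediabetes", "u_t2d_undiagnosed",
                   "u_t2d_phc", "u_t2d_secondary", "u_cvd")}
ZERO_STATE_COSTS = {k: 0.0 for k in
                    ("c_t2d_phc", "c_t2d_secondary", "c_cvd", "c_prolanis_highrisk")}


def constant_q_table(q: float, start=40, cap=110) -> LifeTable:
    qs = [q] * (cap - start + 1)
    qs[-1] = 1.0
    return LifeTable(tuple(range(start, cap + 1)), tuple(qs))


class TestTransitionMatrix:
    def test_no_transitions_no_mortality_gives_identity(self, ps):
        psx = ps.with_values(ZERO_TRANSITIONS)
        lt0 = constant_q_table(0.0)
        M = build_transition_matrix(psx, 40, lt0)
        assert np.allclose(M, np.eye(M.shape[0]))

    def test_mortality_first_composition(self, ps):
        # single exit PRE -> T2D at 0.5 with qx = 0.1: survivors split evenly
        psx = ps.with_values({**ZERO_TRANSITIONS, "tp_pre_to_t2d": 0.5})
        lt1 = constant_q_table(0.1)
        space = build_state_space(psx)
        M = build_transition_matrix(psx, 40, lt1, space)
        i = space.index[Compartment(State.PREDIABETES)]
        j = space.index[Compartment(State.T2D_UNDIAGNOSED)]
        assert M[i, i] == pytest.approx(0.45)
        assert M[i, j] == pytest.approx(0.45)
        assert M[i, space.dead_index] == pytest.approx(0.10)

    def test_unit_hazard_ratio_equalises_cvd_risk(self, ps):
        psx = ps.with_values({"hr_cvd_undiagnosed": 1.0})
        space = build_state_space(psx)
        M = build_transition_matrix(psx, 40, constant_q_table(0.0), space)
        cvd = space.index[Compartment(State.CVD)]
        undiag = space.index[Compartment(State.T2D_UNDIAGNOSED)]
        dx = space.index[Compartment(State.T2D_DIAGNOSED, setting="phc")]
        assert M[undiag, cvd] == pytest.approx(M[dx, cvd])

    def test_elevated_hazard_raises_cvd_risk_for_undiagnosed(self, ps):
        space = build_state_space(ps)
        M = build_transition_matrix(ps, 40, constant_q_table(0.0), space)
        cvd = space.index[Compartment(State.CVD)]
        undiag = space.index[Compartment(State.T2D_UNDIAGNOSED)]
        dx = space.index[Compartment(State.T2D_DIAGNOSED, setting="phc")]
        assert M[undiag, cvd] > M[dx, cvd]
        # complementary-log composition: 1-(1-p)^HR
        p = ps["tp_t2d_to_cvd"]
        assert M[undiag, cvd] == pytest.approx(1 - (1 - p) ** ps["hr_cvd_undiagnosed"])

    def test_rows_are_stochastic_at_every_age(self, ps, lt):
        space = build_state_space(ps)
        for age in (40, 60, 80, 105):
            M = build_transition_matrix(ps, age, lt, space)
            assert np.allclose(M.sum(axis=1), 1.0, atol=1e-12)
            assert (M >= -1e-15).all()

    def test_infeasible_transition_mass_is_fatal(self, ps):
        bad = ps.with_values({"tp_undiag_detection": 0.9, "tp_t2d_to_cvd": 0.3})
        with pytest.raises(ValueError, match="T2D_UNDIAGNOSED"):
            build_transition_matrix(bad, 40, constant_q_table(0.0))


class TestRunMarkov:
    def test_geometric_survival_yields_unit_qaly(self, ps):
        # utility 1 everywhere, q=0.5 per cycle, r=0: QALYs/person = sum 0.5^t = 1
        psx = ps.with_values({**ZERO_TRANSITIONS, **UNIT_UTILITIES,
                              **ZERO_STATE_COSTS, "discount_rate": 0.0})
        lt5 = constant_q_table(0.5)
        tree = screen_cohort(psx, Strategy.REFERENCE)
        trace = run_markov(tree, psx, lt5)
        res = accrue_outcomes(trace, psx, 0.0)
        assert res.total_qaly == pytest.approx(psx["cohort_size"], rel=1e-9)

    def test_no_mortality_keeps_occupancy_constant(self, ps):
        psx = ps.with_values(ZERO_TRANSITIONS)
        lt0 = constant_q_table(0.0)
        tree = screen_cohort(psx, Strategy.SCREENING)
        trace = run_markov(tree, psx, lt0)
        assert np.allclose(trace.occupancy[0], trace.occupancy[-1])

    def test_conservation_and_monotone_death(self, ps, lt):
        tree = screen_cohort(ps, Strategy.SCREENING_EDUCATION)
        trace = run_markov(tree, ps, lt)
        assert np.allclose(trace.occupancy.sum(axis=1), ps["cohort_size"], atol=1e-6)
        dead = trace.occupancy[:, trace.space.dead_index]
        assert (np.diff(dead) >= -1e-9).all()
        assert dead[-1] >= ps["cohort_size"] * (1 - 1e-6)

    def test_discounting_is_monotone_decreasing(self, ps, lt):
        tree = screen_cohort(ps, Strategy.SCREENING)
        trace = run_markov(tree, ps, lt)
        totals = [accrue_outcomes(trace, ps.with_values({"discount_rate": r}), 0.0)
                  for r in (0.0, 0.03, 0.05)]
        assert totals[0].total_cost > totals[1].total_cost > totals[2].total_cost
        assert totals[0].total_qaly > totals[1].total_qaly > totals[2].total_qaly

    def test_raising_utility_raises_qalys(self, ps, lt):
        tree = screen_cohort(ps, Strategy.SCREENING)
        base = accrue_outcomes(run_markov(tree, ps, lt), ps, 0.0).total_qaly
        psx = ps.with_values({"u_cvd": min(1.0, ps["u_cvd"] + 0.1)})
        up = accrue_outcomes(run_markov(screen_cohort(psx, Strategy.SCREENING), psx, lt), psx, 0.0)
        assert up.total_qaly > base

    def test_raising_state_cost_raises_total_cost(self, ps, lt):
        tree = screen_cohort(ps, Strategy.SCREENING)
        base = accrue_outcomes(run_markov(tree, ps, lt), ps, 0.0).total_cost
        psx = ps.with_values({"c_cvd": ps["c_cvd"] * 1.5})
        up = accrue_outcomes(run_markov(screen_cohort(psx, Strategy.SCREENING), psx, lt), psx, 0.0)
        assert up.total_cost > base


class TestAccrual:
    def _flat_cost_trace(self, ps, cycles, cost_per_cycle):
        space = build_state_space(ps)
        k = len(space)
        occ = np.zeros((cycles + 1, k))
        occ[:, space.dead_index] = ps["cohort_size"]  # occupancy irrelevant here
        cost = np.full(cycles + 1, float(cost_per_cycle))
        cost[0] = 0.0
        return MarkovTrace(
            occupancy=occ, ages=np.arange(40, 41 + cycles),
            cycle_cost=cost, cycle_qaly=np.zeros(cycles + 1),
            cbhi_cycle_costs=np.zeros(cycles + 1),
            cycle_screened=np.zeros(cycles + 1),
            space=space, cohort_size=ps["cohort_size"],
        )

    def test_zero_rate_gives_undiscounted_sums(self, ps):
        trace = self._flat_cost_trace(ps, 10, 100.0)
        res = accrue_outcomes(trace, ps.with_values({"discount_rate": 0.0}), 0.0)
        assert res.total_cost == pytest.approx(1000.0)

    def test_year_24_discount_term(self, ps):
        # 100/1.03^24 ~ 49.19 (1.03^24 ~ 2.0328)
        t24 = self._flat_cost_trace(ps, 24, 0.0)
        t24.cycle_cost[24] = 100.0
        t23 = self._flat_cost_trace(ps, 23, 0.0)
        res = accrue_outcomes(t24, ps, 0.0)
        assert res.total_cost == pytest.approx(100.0 / 1.03**24)
        assert res.total_cost == pytest.approx(49.19, abs=0.01)

    def test_tree_cost_enters_undiscounted(self, ps):
        trace = self._flat_cost_trace(ps, 5, 0.0)
        res = accrue_outcomes(trace, ps, 1234.5)
        assert res.cbhi_cost == pytest.approx(1234.5)
        assert res.total_cost == pytest.approx(1234.5)


class TestLifeExpectancy:
    def test_constant_half_mortality_gives_one_year(self):
        assert life_expectancy(constant_q_table(0.5), 40) == pytest.approx(1.0, rel=1e-9)

    def test_certain_death_gives_zero(self):
        assert life_expectancy(constant_q_table(1.0), 40) == 0.0

    def test_engine_reproduces_closed_form_on_two_state_model(self, ps):
        # all-cause mortality only, utility 1, r=0: engine total QALYs per
        # person equal the survival-product sum
        lt = gompertz_life_table(5e-4, 0.085, 40, 110)
        psx = ps.with_values({**ZERO_TRANSITIONS, **UNIT_UTILITIES,
                              **ZERO_STATE_COSTS, "discount_rate": 0.0})
        tree = screen_cohort(psx, Strategy.REFERENCE)
        res = accrue_outcomes(run_markov(tree, psx, lt), psx, 0.0)
        expected = life_expectancy(lt, 40) * psx["cohort_size"]
        assert res.total_qaly == pytest.approx(expected, rel=1e-9)
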