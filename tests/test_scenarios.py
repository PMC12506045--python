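"""Scenario analyses: rescreening schedules, grids, knowledge-gain search."""

import numpy as np
import pytest

from t2dcea.economics import incremental
from t2dcea.markov_engine import Compartment, State, run_markov
from t2dcea.pipeline import run_strategy
from t2dcea.scenarios import (
    RescreenSchedule,
    grid_minimum,
    knowledge_gain_for_cost_saving,
    run_repeated,
)
from t2dcea.params import LifeTable
from t2dcea.screening_tree import Strategy, screen_cohort


def _deathless_table(start=40, cap=110) -> LifeTable:
    qs = [0.0] * (cap - start + 1)
    qs[-1] = 1.0
    return LifeTable(tuple(range(start, cap + 1)), tuple(qs))


class TestRepeated:
    def test_zero_participation_reproduces_one_time_bit_exactly(self, ps, lt):
        for strat in ("screening", "screening_education"):
            one = run_strategy(ps, lt, strat)
            rep = run_repeated(ps, RescreenSchedule(window=10, participation=0.0),
                               strat, lt)
            assert rep.total_cost == one.total_cost
            assert rep.total_qaly == one.total_qaly
            assert rep.cbhi_cost == one.cbhi_cost

    def test_zero_window_reproduces_one_time_bit_exactly(self, ps, lt):
        one = run_strategy(ps, lt, "screening")
        rep = run_repeated(ps, RescreenSchedule(window=0, participation=0.06),
                           "screening", lt)
        assert rep.total_cost == one.total_cost
        assert rep.total_qaly == one.total_qaly

    def test_rescreening_adds_cost_and_health_gain(self, ps, lt):
        # repeated > one-time in both cost and QALYs, as in the published table
        for strat in ("screening", "screening_education"):
            one = run_strategy(ps, lt, strat)
            rep = run_repeated(ps, RescreenSchedule.from_parameters(ps), strat, lt)
            assert rep.total_cost > one.total_cost
            assert rep.total_qaly > one.total_qaly
            assert rep.cbhi_cost > one.cbhi_cost

    def test_single_event_detection_flow_arithmetic(self, ps, lt):
        # one rescreen event in a frozen model: detected flow out of the
        # flagged undiagnosed compartment = mass x participation x Se x adherence
        frozen = ps.with_values({
            "tp_ngt_low_to_mod": 0.0, "tp_ngt_mod_to_high": 0.0,
            "tp_ngt_low_to_pre": 0.0, "tp_ngt_mod_to_pre": 0.0,
            "tp_ngt_high_to_pre": 0.0, "tp_pre_to_t2d": 0.0,
            "tp_undiag_detection": 0.0, "tp_t2d_to_cvd": 0.0,
            "tp_cvd_case_fatality": 0.0,
        })
        tree = screen_cohort(frozen, Strategy.SCREENING)
        flagged0 = tree.flagged_false_negatives["not_educated"]
        assert flagged0 > 0
        sched = RescreenSchedule(window=1, participation=0.5, triennial_cycles=())
        from t2dcea.scenarios import _rescreen_hook

        # mortality-free life table so the hook's flow is the only change
        trace = run_markov(tree, frozen, _deathless_table(), _rescreen_hook(frozen, sched))
        space = trace.space
        phc = space.index[Compartment(State.T2D_DIAGNOSED, False, setting="phc")]
        detected = trace.occupancy[1, phc] - trace.occupancy[0, phc]
        expected = flagged0 * 0.5 * frozen["rcbg_sensitivity"] * frozen["referral_adherence"]
        assert detected == pytest.approx(expected, rel=1e-12)

    def test_screened_count_conservation(self, ps, lt):
        sched = RescreenSchedule.from_parameters(ps)
        tree = screen_cohort(ps, Strategy.SCREENING)
        from t2dcea.scenarios import _rescreen_hook

        trace = run_markov(tree, ps, lt, _rescreen_hook(ps, sched))
        # screened persons only during the window, positive each scheduled year
        assert (trace.cycle_screened[11:] == 0).all()
        assert (trace.cycle_screened[1:11] > 0).all()

    def test_window_beyond_horizon_is_fatal(self, ps, lt):
        with pytest.raises(ValueError, match="window"):
            run_repeated(ps, RescreenSchedule(window=100, participation=0.06),
                         "screening", lt)

    def test_reference_cannot_be_rescreened(self, ps, lt):
        with pytest.raises(ValueError):
            run_repeated(ps, RescreenSchedule(), "reference", lt)


class TestGrid:
    def test_grid_matches_independent_single_runs(self, ps, lt):
        grid = np.array([0.05, 0.3, 0.8])
        table, _ = grid_minimum(ps, lt, "adherence", threshold=ps["wtp_gdp_per_capita"],
                                grid=grid)
        for _, row in table.iterrows():
            psl = ps.with_values({"referral_adherence": row["level"],
                                  "rescreen_adherence": row["level"]})
            ref = run_strategy(psl, lt, "reference")
            alt = run_strategy(psl, lt, "screening")
            ce = incremental(ref, alt)
            assert row["delta_cost"] == pytest.approx(ce.delta_cost, rel=1e-12)
            assert row["delta_qaly"] == pytest.approx(ce.delta_qaly, rel=1e-12)

    def test_minimum_is_first_qualifying_level(self, ps, lt):
        table, minimum = grid_minimum(ps, lt, "uptake", threshold=ps["wtp_gdp_per_capita"],
                                      grid=np.array([0.05, 0.5, 1.0]))
        qualifying = table[table["cost_effective"]]
        if len(qualifying):
            assert minimum == qualifying["level"].iloc[0]
        else:
            assert minimum is None

    def test_boundary_qualifies_at_first_level(self, ps, lt):
        # an enormous threshold qualifies immediately at the 5% boundary
        _, minimum = grid_minimum(ps, lt, "uptake", threshold=1e12,
                                  grid=np.array([0.05, 0.10]))
        assert minimum == 0.05

    def test_zero_threshold_with_positive_cost_gives_none(self, ps, lt):
        table, minimum = grid_minimum(ps, lt, "uptake", threshold=0.0,
                                      grid=np.array([0.05, 0.10]))
        if (table["delta_cost"] > 0).all():
            assert minimum is None

    def test_empty_grid_is_fatal(self, ps, lt):
        with pytest.raises(ValueError, match="empty"):
            grid_minimum(ps, lt, "uptake", threshold=1.0, grid=np.array([]))


class TestKnowledgeSearch:
    def test_no_risk_reduction_can_never_save_costs(self, ps, lt):
        psx = ps.with_values({"rr_lifestyle": 0.0})
        assert knowledge_gain_for_cost_saving(psx, lt, step=2.0) is None

    def test_threshold_exists_on_canonical_set_and_matches_bisection(self, ps, lt):
        step = 0.25
        dk = knowledge_gain_for_cost_saving(ps, lt, step=step)
        assert dk is not None
        assert 0.86 < dk <= ps["knowledge_scale_max_gain"]

        # bisection oracle on the same cost difference
        ref = run_strategy(ps, lt, "reference")

        def delta_cost(k):
            alt = run_strategy(ps.with_values({"atet_knowledge": k}), lt,
                               "screening_education")
            return alt.total_cost - ref.total_cost

        lo, hi = 0.0, ps["knowledge_scale_max_gain"]
        assert delta_cost(hi) <= 0 < delta_cost(lo)
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if delta_cost(mid) <= 0:
                hi = mid
            else:
                lo = mid
        assert abs(dk - hi) <= step

    def test_nonpositive_step_is_fatal(self, ps, lt):
        with pytest.raises(ValueError):
            knowledge_gain_for_cost_saving(ps, lt, step=0.0)
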