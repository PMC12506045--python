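"""PSA machinery: moment fits, reproducible draws, CEAC identities, OWSA."""

import numpy as np
import pandas as pd
import pytest

from t2dcea.uncertainty import (
    PSAResult,
    beta_from_moments,
    draw_parameters,
    gamma_from_moments,
    owsa,
    run_psa,
)


class TestMomentFits:
    def test_beta_method_of_moments(self):
        a, b = beta_from_moments(0.7, 0.1)
        assert (a, b) == (pytest.approx(14.0), pytest.approx(6.0))

    def test_gamma_method_of_moments(self):
        shape, scale = gamma_from_moments(100.0, 20.0)
        assert (shape, scale) == (pytest.approx(25.0), pytest.approx(4.0))

    def test_infeasible_beta_moments_are_fatal(self):
        with pytest.raises(ValueError, match="infeasible"):
            beta_from_moments(0.5, 0.6)


class TestDraws:
    def test_fixed_parameters_never_vary(self, ps):
        s = draw_parameters(ps, 200, seed=1)
        assert "discount_rate" not in s.draws.columns
        assert "cohort_size" not in s.draws.columns

    def test_reproducible_from_seed(self, ps):
        a = draw_parameters(ps, 300, seed=99)
        b = draw_parameters(ps, 300, seed=99)
        pd.testing.assert_frame_equal(a.draws, b.draws)

    def test_different_seeds_differ(self, ps):
        a = draw_parameters(ps, 100, seed=1)
        b = draw_parameters(ps, 100, seed=2)
        assert not a.draws.equals(b.draws)

    def test_prevalence_draws_stay_on_simplex(self, ps):
        s = draw_parameters(ps, 500, seed=3)
        prev = [c for c in s.draws.columns if c.startswith("prev_")]
        assert np.allclose(s.draws[prev].sum(axis=1), 1.0, atol=1e-12)

    def test_probability_draws_stay_in_unit_interval(self, ps):
        s = draw_parameters(ps, 500, seed=3)
        for name in s.draws.columns:
            if ps.param(name).kind in ("probability", "utility"):
                col = s.draws[name]
                assert (col >= 0).all() and (col <= 1).all()

    def test_sample_moments_match_specs_within_three_se(self, ps):
        s = draw_parameters(ps, 10_000, seed=20220101)
        for name in s.draws.columns:
            x = s.draws[name].to_numpy()
            se_mean = x.std(ddof=1) / np.sqrt(len(x))
            if se_mean == 0:
                continue
            z = (x.mean() - ps[name]) / se_mean
            assert abs(z) < 3.0, f"{name}: z={z:.2f}"


def _manual_psa_result(dc, de, ref_cost=1000.0, ref_qaly=100.0):
    n = len(dc)
    costs = pd.DataFrame({
        "reference": np.full(n, ref_cost),
        "alt": ref_cost + np.asarray(dc, dtype=float),
    })
    qalys = pd.DataFrame({
        "reference": np.full(n, ref_qaly),
        "alt": ref_qaly + np.asarray(de, dtype=float),
    })
    return PSAResult(costs, qalys, "reference", np.linspace(0, 3e4, 4))


class TestCEAC:
    def test_ceac_by_nmb_enumeration(self):
        # draws (ΔC, ΔE): NMB(15) = {5, 20, 10, −45} → 3/4 above zero
        r = _manual_psa_result([10, -5, 20, 30], [1, 1, 2, -1])
        assert r.probability_cost_effective("alt", 15.0) == pytest.approx(0.75)

    def test_ceac_at_zero_wtp_is_probability_of_cost_saving(self):
        r = _manual_psa_result([10, -5, 20, -30], [1, 1, 2, -1])
        dc, _ = r.deltas("alt")
        assert r.probability_cost_effective("alt", 0.0) == (dc < 0).mean()

    def test_ceac_monotone_when_all_effects_positive(self):
        rng = np.random.default_rng(0)
        r = _manual_psa_result(rng.normal(10, 30, 400), rng.uniform(0.1, 2.0, 400))
        curve = r.ceac("alt", np.linspace(0, 200, 50))
        assert (np.diff(curve) >= -1e-12).all()

    def test_all_fixed_draws_make_a_step_ceac(self, ps, lt):
        fixed = ps.with_values({})  # same values; use a 5-iteration constant sample
        s = draw_parameters(ps, 5, seed=1)
        const = s.draws.iloc[[0] * 5].reset_index(drop=True)
        sample = type(s)(const, s.seed, 5)
        r = run_psa(fixed, lt, sample, ["reference", "screening"])
        dc, de = r.deltas("screening")
        icer = dc[0] / de[0]
        assert np.allclose(dc, dc[0]) and np.allclose(de, de[0])
        assert r.probability_cost_effective("screening", icer * 0.99) == 0.0
        assert r.probability_cost_effective("screening", icer * 1.01) == 1.0


class TestFullModelPSA:
    def test_bit_identical_rerun_under_fixed_seed(self, ps, lt):
        s = draw_parameters(ps, 40, seed=77)
        r1 = run_psa(ps, lt, s, ["reference", "screening"])
        r2 = run_psa(ps, lt, draw_parameters(ps, 40, seed=77),
                     ["reference", "screening"])
        pd.testing.assert_frame_equal(r1.costs, r2.costs)
        pd.testing.assert_frame_equal(r1.qalys, r2.qalys)

    def test_deterministic_run_within_psa_spread(self, ps, lt):
        # the deterministic totals sit inside the PSA cloud of totals
        from t2dcea.pipeline import run_strategy

        s = draw_parameters(ps, 150, seed=5)
        r = run_psa(ps, lt, s, ["reference", "screening"])
        det = run_strategy(ps, lt, "screening")
        lo, hi = np.percentile(r.costs["screening"], [0.5, 99.5])
        assert lo < det.total_cost < hi


class TestOWSA:
    def test_pinning_to_base_leaves_icer_unchanged(self, ps, lt):
        s = draw_parameters(ps, 30, seed=8)
        base = owsa(ps, lt, s, "c_cvd", "base", strategy="screening")
        # pinning c_cvd to its base in every draw vs the mean over free draws
        # differs; but pinning twice to the same value is bit-identical
        again = owsa(ps, lt, s, "c_cvd", "base", strategy="screening")
        assert base.delta_cost == again.delta_cost
        assert base.delta_qaly == again.delta_qaly

    def test_pinning_irrelevant_parameter_changes_nothing(self, ps, lt):
        # education-material cost never enters the screening-only strategy
        s = draw_parameters(ps, 30, seed=8)
        lo = owsa(ps, lt, s, "pc_education_materials", "low", "screening")
        hi = owsa(ps, lt, s, "pc_education_materials", "high", "screening")
        assert lo.delta_cost == pytest.approx(hi.delta_cost, abs=1e-9)
        assert lo.delta_qaly == pytest.approx(hi.delta_qaly, abs=1e-12)

    def test_phc_treatment_cost_drives_incremental_cost_up(self, ps, lt):
        # primary-care diabetes care exists only under screening: pinning its
        # cost high must raise ΔC relative to pinning it low
        s = draw_parameters(ps, 30, seed=8)
        lo = owsa(ps, lt, s, "c_t2d_phc", "low", "screening")
        hi = owsa(ps, lt, s, "c_t2d_phc", "high", "screening")
        assert hi.delta_cost > lo.delta_cost

    def test_unknown_parameter_is_fatal(self, ps, lt):
        s = draw_parameters(ps, 5, seed=8)
        with pytest.raises(KeyError):
            owsa(ps, lt, s, "nonexistent", "low")
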