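"""Probabilistic and one-way sensitivity analysis.

The probabilistic base case samples every uncertain parameter from its
declared distribution (beta / gamma by method of moments, truncated normal,
lognormal) and re-runs the full tree-plus-Markov pipeline for every
strategy on the *same* parameter draw (common random numbers), 10 000
iterations by default.  Expected costs and QALYs are iteration means;
uncertainty is summarised as a cost-effectiveness plane and acceptability
curves CEAC(λ) = P(NMB(λ) > 0).

One-way sensitivity re-uses the same stored draw set with a single
parameter pinned to its low or high bound in every iteration, so the shift
in the expectation isolates that parameter's influence from Monte-Carlo
noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .economics import CEResult, StrategyResult, incremental
from .params import Family, KIND_RANGES, LifeTable, ParameterSet, PREVALENCE_KEYS
from .pipeline import run_strategy
from .scenarios import RescreenSchedule, run_repeated
from .screening_tree import Strategy

__all__ = [
    "PSASample",
    "PSAResult",
    "beta_from_moments",
    "gamma_from_moments",
    "draw_parameters",
    "run_psa",
    "owsa",
    "tornado",
    "STRATEGY_RUNNERS",
]


def beta_from_moments(mean: float, se: float) -> tuple[float, float]:
    """Method-of-moments beta shape parameters.

    nu = m(1−m)/s² − 1 must be positive (moment feasibility); then
    α = m·nu and β = (1−m)·nu.
    """
    if not (0.0 < mean < 1.0):
        raise ValueError(f"beta mean must be in (0,1); got {mean}")
    if se * se >= mean * (1.0 - mean):
        raise ValueError(f"infeasible beta moments: se={se}, mean={mean}")
    nu = mean * (1.0 - mean) / (se * se) - 1.0
    return mean * nu, (1.0 - mean) * nu


def gamma_from_moments(mean: float, se: float) -> tuple[float, float]:
    """Method-of-moments gamma (shape, scale) = (m²/s², s²/m)."""
    if mean <= 0 or se <= 0:
        raise ValueError("gamma requires positive mean and se")
    return mean * mean / (se * se), se * se / mean


@dataclass
class PSASample:
    """Stored draw matrix (iterations × uncertain parameters)."""

    draws: pd.DataFrame
    seed: int
    n: int
    rejected: int = 0

    def pinned(self, name: str, value: float) -> "PSASample":
        d = self.draws.copy()
        if name not in d.columns:
            raise KeyError(f"unknown uncertain parameter {name!r}")
        d[name] = value
        return PSASample(d, self.seed, self.n, self.rejected)


def _draw_one(rng, fam: Family, mean: float, se, ci_low, ci_high, kind: str, n: int):
    if fam is Family.FIXED or se in (None, 0.0) and ci_low is None:
        return np.full(n, mean)
    if fam is Family.BETA:
        a, b = beta_from_moments(mean, se)
        return stats.beta.rvs(a, b, size=n, random_state=rng)
    if fam is Family.GAMMA:
        shape, scale = gamma_from_moments(mean, se)
        return stats.gamma.rvs(shape, scale=scale, size=n, random_state=rng)
    if fam is Family.NORMAL:
        lo, hi = KIND_RANGES.get(kind, KIND_RANGES["other"])
        a, b = (lo - mean) / se, (hi - mean) / se
        return stats.truncnorm.rvs(a, b, loc=mean, scale=se, size=n, random_state=rng)
    if fam is Family.LOGNORMAL:
        if ci_low is not None and ci_high is not None:
            sigma = (np.log(ci_high) - np.log(ci_low)) / (2.0 * 1.959963984540054)
            mu = np.log(mean)
        else:
            # moment-matching: keeps E[X] = mean
            sigma2 = np.log1p((se / mean) ** 2)
            sigma = np.sqrt(sigma2)
            mu = np.log(mean) - sigma2 / 2.0
        return stats.lognorm.rvs(sigma, scale=np.exp(mu), size=n, random_state=rng)
    raise ValueError(f"unknown family {fam}")


def _valid_rows(draws: pd.DataFrame, ps: ParameterSet) -> np.ndarray:
    """Vectorised feasibility screen for drawn transition combinations."""
    def col(name):
        return draws[name].to_numpy() if name in draws.columns else np.full(len(draws), ps[name])

    ok = np.ones(len(draws), dtype=bool)
    ok &= col("tp_ngt_low_to_mod") + col("tp_ngt_low_to_pre") <= 1.0
    ok &= col("tp_ngt_mod_to_high") + col("tp_ngt_mod_to_pre") <= 1.0
    p_cvd_u = 1.0 - (1.0 - col("tp_t2d_to_cvd")) ** col("hr_cvd_undiagnosed")
    ok &= col("tp_undiag_detection") + p_cvd_u <= 1.0
    # education multiplier must stay in (0, 1]
    raw = np.minimum(1.0, col("beta_knowledge_to_lifestyle") * np.maximum(col("atet_knowledge"), 0.0))
    ok &= 1.0 - raw * col("rr_lifestyle") > 0.0
    ok &= col("rr_lifestyle") < 1.0
    return ok


def draw_parameters(ps: ParameterSet, n: int, seed: int) -> PSASample:
    """Sample the uncertain parameters; reproducible from (seed, registry order).

    Prevalence components are drawn jointly and renormalised to the
    simplex.  Iterations whose joint draw violates a model invariant are
    rejected and redrawn (the count is recorded and must stay below 1% of n).
    """
    rng = np.random.default_rng(seed)
    names = ps.uncertain_names

    def sample_block(m: int) -> pd.DataFrame:
        cols = {}
        for name in names:
            p = ps.param(name)
            d = p.dist
            cols[name] = _draw_one(rng, d.family, p.value, d.se, d.ci_low, d.ci_high, p.kind, m)
        df = pd.DataFrame(cols)
        prev = [k for k in PREVALENCE_KEYS if k in df.columns]
        if prev:
            total = df[prev].sum(axis=1)
            df[prev] = df[prev].div(total, axis=0)
        # negative knowledge gains are truncated at no effect
        if "atet_knowledge" in df.columns:
            df["atet_knowledge"] = df["atet_knowledge"].clip(lower=0.0)
        return df

    draws = sample_block(n)
    ok = _valid_rows(draws, ps)
    rejected = int((~ok).sum())
    guard = 0
    while not ok.all():
        m = int((~ok).sum())
        redraw = sample_block(m)
        rok = _valid_rows(redraw, ps)
        idx = np.flatnonzero(~ok)[: len(redraw)]
        accept_idx = idx[rok.to_numpy() if hasattr(rok, "to_numpy") else rok]
        draws.iloc[accept_idx] = redraw[rok].to_numpy()
        ok = _valid_rows(draws, ps)
        rejected += int((~rok).sum())
        guard += 1
        if guard > 100:
            raise RuntimeError("parameter draw rejection did not converge")
    if rejected > 0.01 * n:
        raise RuntimeError(f"rejected {rejected} of {n} draws (> 1%); distributions implausible")
    return PSASample(draws=draws, seed=seed, n=n, rejected=rejected)


# ---------------------------------------------------------------------------
# running the model over a draw set
# ---------------------------------------------------------------------------

def _run_reference(ps, lt):
    return run_strategy(ps, lt, Strategy.REFERENCE)


def _run_screening(ps, lt):
    return run_strategy(ps, lt, Strategy.SCREENING)


def _run_education(ps, lt):
    return run_strategy(ps, lt, Strategy.SCREENING_EDUCATION)


def _run_screening_repeated(ps, lt):
    return run_repeated(ps, RescreenSchedule.from_parameters(ps), Strategy.SCREENING, lt)


def _run_education_repeated(ps, lt):
    return run_repeated(ps, RescreenSchedule.from_parameters(ps), Strategy.SCREENING_EDUCATION, lt)


STRATEGY_RUNNERS = {
    "reference": _run_reference,
    "screening": _run_screening,
    "screening_education": _run_education,
    "screening_repeated": _run_screening_repeated,
    "screening_education_repeated": _run_education_repeated,
}


@dataclass
class PSAResult:
    """Per-iteration (cost, QALY) pairs per strategy under common draws."""

    costs: pd.DataFrame
    qalys: pd.DataFrame
    reference: str
    wtp_grid: np.ndarray

    def expected(self) -> pd.DataFrame:
        """Probabilistic base case: iteration means per strategy."""
        return pd.DataFrame({"cost": self.costs.mean(), "qaly": self.qalys.mean()})

    def deltas(self, strategy: str) -> tuple[np.ndarray, np.ndarray]:
        dc = (self.costs[strategy] - self.costs[self.reference]).to_numpy()
        de = (self.qalys[strategy] - self.qalys[self.reference]).to_numpy()
        return dc, de

    def ceac(self, strategy: str, wtp: np.ndarray | None = None) -> np.ndarray:
        """P(λ·ΔE − ΔC > 0) along the willingness-to-pay grid."""
        wtp = self.wtp_grid if wtp is None else np.asarray(wtp, dtype=float)
        dc, de = self.deltas(strategy)
        return np.array([(w * de - dc > 0).mean() for w in np.atleast_1d(wtp)])

    def probability_cost_effective(self, strategy: str, wtp: float) -> float:
        return float(self.ceac(strategy, np.array([wtp]))[0])

    def incremental_expected(self, strategy: str) -> CEResult:
        exp = self.expected()
        ref = StrategyResult(self.reference, float(exp.loc[self.reference, "cost"]),
                             float(exp.loc[self.reference, "qaly"]), 0.0,
                             float(exp.loc[self.reference, "cost"]))
        alt = StrategyResult(strategy, float(exp.loc[strategy, "cost"]),
                             float(exp.loc[strategy, "qaly"]), 0.0,
                             float(exp.loc[strategy, "cost"]))
        return incremental(ref, alt)


def run_psa(
    ps: ParameterSet,
    lt: LifeTable,
    sample: PSASample,
    strategies: list[str] | None = None,
    wtp_grid: np.ndarray | None = None,
) -> PSAResult:
    """Evaluate every strategy on every draw of the common draw set."""
    strategies = strategies or ["reference", "screening", "screening_education"]
    unknown = set(strategies) - set(STRATEGY_RUNNERS)
    if unknown:
        raise ValueError(f"unknown strategies: {sorted(unknown)}")
    if "reference" not in strategies:
        strategies = ["reference", *strategies]
    if wtp_grid is None:
        gdp = ps["wtp_gdp_per_capita"]
        wtp_grid = np.linspace(0.0, 3.0 * gdp, 301)

    costs = {s: np.empty(sample.n) for s in strategies}
    qalys = {s: np.empty(sample.n) for s in strategies}
    records = sample.draws.to_dict("records")
    for i, row in enumerate(records):
        psi = ps.with_values(row)
        for s in strategies:
            res = STRATEGY_RUNNERS[s](psi, lt)
            costs[s][i] = res.total_cost
            qalys[s][i] = res.total_qaly
    return PSAResult(
        costs=pd.DataFrame(costs),
        qalys=pd.DataFrame(qalys),
        reference="reference",
        wtp_grid=np.asarray(wtp_grid, dtype=float),
    )


def owsa(
    ps: ParameterSet,
    lt: LifeTable,
    sample: PSASample,
    parameter: str,
    bound: str,
    strategy: str = "screening",
) -> CEResult:
    """Expectation over the common draw set with one parameter pinned.

    ``bound`` is 'low', 'high' or 'base'.  Re-running the same stored
    draws with the parameter pinned in every iteration means the change in
    the incremental result reflects only that parameter.
    """
    if parameter not in ps:
        raise KeyError(f"unknown parameter {parameter!r}")
    p = ps.param(parameter)
    lo, hi = p.resolved_bounds(ps["owsa_default_range"])
    value = {"low": lo, "high": hi, "base": p.value}[bound]
    if parameter in sample.draws.columns:
        pinned = sample.pinned(parameter, value)
        base = ps
    else:
        pinned = sample
        base = ps.with_values({parameter: value})
    res = run_psa(base, lt, pinned, ["reference", strategy], wtp_grid=np.array([0.0]))
    exp = res.expected()
    dc = float(exp.loc[strategy, "cost"] - exp.loc["reference", "cost"])
    de = float(exp.loc[strategy, "qaly"] - exp.loc["reference", "qaly"])
    ref = StrategyResult("reference", float(exp.loc["reference", "cost"]),
                         float(exp.loc["reference", "qaly"]), 0.0,
                         float(exp.loc["reference", "cost"]))
    alt = StrategyResult(strategy, float(exp.loc[strategy, "cost"]),
                         float(exp.loc[strategy, "qaly"]), 0.0,
                         float(exp.loc[strategy, "cost"]))
    return incremental(ref, alt)


def tornado(
    ps: ParameterSet,
    lt: LifeTable,
    sample: PSASample,
    parameters: list[str],
    strategy: str = "screening",
) -> pd.DataFrame:
    """One-way results for several parameters, sorted by ICER range."""
    rows = []
    for name in parameters:
        lo = owsa(ps, lt, sample, name, "low", strategy)
        hi = owsa(ps, lt, sample, name, "high", strategy)
        icers = [x.icer for x in (lo, hi) if x.icer is not None]
        rows.append(
            {
                "parameter": name,
                "icer_low": lo.icer if lo.icer is not None else float("nan"),
                "icer_high": hi.icer if hi.icer is not None else float("nan"),
                "range": (max(icers) - min(icers)) if len(icers) == 2 else float("nan"),
            }
        )
    df = pd.DataFrame(rows).set_index("parameter")
    return df.sort_values("range", ascending=False)
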