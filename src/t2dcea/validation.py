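"""Independent cross-checks of the cohort model.

Two oracles that recompute model outputs by a different route than the
production code, used by the test suite and the acceptance script:

* :func:`enumerate_tree` — evaluates the screening cascade by exhaustively
  enumerating every discrete branch path (attend × glycaemic state × test
  result × referral × adherence) and summing path probabilities, instead of
  the vectorised cohort-fraction arithmetic of ``screen_cohort``.
* :func:`microsimulate` — propagates the cohort as integer head-counts with
  multinomial transition sampling (an individual-level stochastic
  simulation in aggregated form) and summarises a digest of occupancies and
  discounted totals in batches, so the deterministic cohort expectation can
  be compared against the empirical mean within Monte-Carlo error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .markov_engine import (
    MarkovTrace,
    State,
    build_state_space,
    build_transition_matrix,
    map_tree_to_compartments,
)
from .params import LifeTable, ParameterSet
from .screening_tree import Group, STRATA, Strategy, TreeOutput

__all__ = ["enumerate_tree", "microsimulate", "MicrosimDigest", "compare_digest"]


def enumerate_tree(ps: ParameterSet, strategy: Strategy | str) -> dict[tuple[Group, str], float]:
    """Exhaustive branch-path enumeration of the screening cascade.

    Walks every (attendance, glycaemic state, test outcome, adherence)
    path with its joint probability and accumulates expected persons per
    end group and education stratum.  Independent of ``screen_cohort``'s
    grouped arithmetic; agreement is expected to ~1e−15 relative.
    """
    strategy = Strategy(strategy)
    n = ps["cohort_size"]
    prev = ps.prevalence
    se, sp = ps["rcbg_sensitivity"], ps["rcbg_specificity"]
    adh = ps["referral_adherence"]
    uptake = 0.0 if strategy is Strategy.REFERENCE else ps["uptake"]
    edu_stratum = "educated" if strategy is Strategy.SCREENING_EDUCATION else "not_educated"

    state_group = {
        "prev_t2d_undiagnosed": None,  # handled explicitly
        "prev_prediabetes": Group.PREDIABETES,
        "prev_ngt_low": Group.NGT_LOW,
        "prev_ngt_mod": Group.NGT_MOD,
        "prev_ngt_high": None,  # handled explicitly
    }
    out = {(g, s): 0.0 for g in Group for s in STRATA}

    for attend, p_att in (("yes", uptake), ("no", 1.0 - uptake)):
        stratum = edu_stratum if attend == "yes" else "not_educated"
        for key, p_state in prev.items():
            base = n * p_att * p_state
            if base == 0.0:
                continue
            if attend == "no":
                if key == "prev_t2d_undiagnosed":
                    out[(Group.T2D_UNDIAGNOSED, stratum)] += base
                elif key == "prev_ngt_high":
                    out[(Group.NGT_HIGH_UNTREATED, stratum)] += base
                else:
                    out[(state_group[key], stratum)] += base
                continue
            if key == "prev_t2d_undiagnosed":
                for test, p_test in (("pos", se), ("neg", 1.0 - se)):
                    if test == "neg":
                        out[(Group.T2D_UNDIAGNOSED, stratum)] += base * p_test
                        continue
                    for go, p_go in (("adhere", adh), ("refuse", 1.0 - adh)):
                        dest = Group.T2D_DIAGNOSED_PHC if go == "adhere" else Group.T2D_UNDIAGNOSED
                        out[(dest, stratum)] += base * p_test * p_go
            elif key == "prev_ngt_high":
                # referred irrespective of the test result
                for test, p_test in (("pos", 1.0 - sp), ("neg", sp)):
                    for go, p_go in (("adhere", adh), ("refuse", 1.0 - adh)):
                        dest = Group.NGT_HIGH_TREATED if go == "adhere" else Group.NGT_HIGH_UNTREATED
                        out[(dest, stratum)] += base * p_test * p_go
            else:
                group = state_group[key]
                for test, p_test in (("pos", 1.0 - sp), ("neg", sp)):
                    if test == "neg":
                        out[(group, stratum)] += base * p_test
                        continue
                    for go, p_go in (("adhere", adh), ("refuse", 1.0 - adh)):
                        # false positive: confirmed non-diabetic either way
                        out[(group, stratum)] += base * p_test * p_go
    return out


@dataclass
class MicrosimDigest:
    """Batch summaries from the head-count microsimulation.

    ``values`` has one row per batch; columns are the digest quantities
    (state occupancies at probe cycles, scaled to the cohort, plus
    discounted treatment cost and QALY totals).
    """

    columns: list[str]
    values: np.ndarray
    walkers_per_batch: int
    n_batches: int

    def mean(self) -> np.ndarray:
        return self.values.mean(axis=0)

    def se(self) -> np.ndarray:
        return self.values.std(axis=0, ddof=1) / np.sqrt(self.n_batches)


_PROBE_CYCLES = (10, 20, 30)


def _digest_from_trace(trace: MarkovTrace, ps: ParameterSet) -> tuple[list[str], np.ndarray]:
    """State-aggregated digest of a (deterministic or simulated) trace."""
    space = trace.space
    agg = {st: [i for i, c in enumerate(space.compartments) if c.state is st] for st in State}
    cols, vals = [], []
    T = trace.occupancy.shape[0] - 1
    for t in _PROBE_CYCLES:
        tt = min(t, T)
        for st in State:
            cols.append(f"occ_c{t}_{st.value}")
            vals.append(float(trace.occupancy[tt, agg[st]].sum()))
    r = ps["discount_rate"]
    disc = (1.0 + r) ** (-np.arange(T + 1, dtype=float))
    cols += ["disc_cost", "disc_qaly"]
    vals += [float(trace.cycle_cost @ disc), float(trace.cycle_qaly @ disc)]
    return cols, np.array(vals)


def microsimulate(
    tree: TreeOutput,
    ps: ParameterSet,
    lt: LifeTable,
    n_walkers: int = 200_000,
    n_batches: int = 20,
    seed: int = 12345,
) -> MicrosimDigest:
    """Head-count stochastic simulation of the Markov phase.

    Walkers are allocated to starting compartments by multinomial sampling
    of the tree occupancy, then advanced with per-compartment multinomial
    transition draws from the full age-specific matrix.  Results are scaled
    to the cohort size and digested per batch so that the batch spread
    yields a Monte-Carlo standard error for each digest quantity.
    """
    space = build_state_space(ps)
    x0 = map_tree_to_compartments(tree, space)
    n = ps["cohort_size"]
    p0 = x0 / x0.sum()
    start_age, age_cap = int(ps["start_age"]), int(ps["age_cap"])
    rng = np.random.default_rng(seed)
    per_batch = n_walkers // n_batches

    matrices = {
        age: build_transition_matrix(ps, age, lt, space)
        for age in range(start_age, age_cap)
    }
    dead = space.dead_index

    batch_rows = []
    cols = None
    for _b in range(n_batches):
        counts = rng.multinomial(per_batch, p0).astype(np.int64)
        occ = [counts * (n / per_batch)]
        cycle_cost = [0.0]
        cycle_qaly = [0.0]
        t = 0
        while True:
            age = start_age + t
            if age >= age_cap or counts[dead] >= per_batch:
                break
            t += 1
            M = matrices[age]
            nxt = np.zeros_like(counts)
            for i in np.flatnonzero(counts):
                if i == dead:
                    nxt[dead] += counts[dead]
                    continue
                nxt += rng.multinomial(counts[i], M[i])
            counts = nxt
            scaled = counts * (n / per_batch)
            occ.append(scaled)
            cycle_cost.append(float(scaled @ space.costs))
            cycle_qaly.append(float(scaled @ space.utilities))
        sim_trace = MarkovTrace(
            occupancy=np.vstack(occ),
            ages=np.arange(start_age, start_age + len(occ)),
            cycle_cost=np.array(cycle_cost),
            cycle_qaly=np.array(cycle_qaly),
            cbhi_cycle_costs=np.zeros(len(occ)),
            cycle_screened=np.zeros(len(occ)),
            space=space,
            cohort_size=n,
        )
        cols, vals = _digest_from_trace(sim_trace, ps)
        batch_rows.append(vals)
    return MicrosimDigest(cols, np.vstack(batch_rows), per_batch, n_batches)


def compare_digest(
    trace: MarkovTrace, ps: ParameterSet, digest: MicrosimDigest, min_se: float = 1e-9
) -> np.ndarray:
    """z-scores of the deterministic trace against the microsim digest.

    Entries whose Monte-Carlo SE is numerically zero (e.g. empty states)
    are compared by absolute difference against ``min_se``.
    """
    cols, det = _digest_from_trace(trace, ps)
    assert cols == digest.columns
    se = np.maximum(digest.se(), min_se)
    return (det - digest.mean()) / se
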