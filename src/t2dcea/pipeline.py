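"""End-to-end strategy evaluation and canonical fixtures.

``run_strategy`` chains the decision tree, the Markov projection and the
discounted accrual into one call; ``canonical_parameter_set`` loads the
seed-0 synthetic parameter registry shipped with the package, which every
example and test uses as its common fixture.
"""

from __future__ import annotations

from importlib import resources

from .economics import StrategyResult, incremental, make_report
from .markov_engine import CycleHook, accrue_outcomes, run_markov
from .params import LifeTable, ParameterSet, ParameterSet as _PS, load_parameters
from .screening_tree import Strategy, screen_cohort

__all__ = [
    "run_strategy",
    "run_all_strategies",
    "canonical_parameter_set",
    "canonical_life_table",
]

STRATEGIES = (Strategy.REFERENCE, Strategy.SCREENING, Strategy.SCREENING_EDUCATION)


def run_strategy(
    ps: ParameterSet,
    lt: LifeTable,
    strategy: Strategy | str,
    cycle_hook: CycleHook | None = None,
    label: str | None = None,
) -> StrategyResult:
    """Tree → Markov → discounted totals for one strategy."""
    strategy = Strategy(strategy)
    tree = screen_cohort(ps, strategy)
    trace = run_markov(tree, ps, lt, cycle_hook=cycle_hook)
    return accrue_outcomes(trace, ps, tree.tree_cost, strategy=label or strategy.value)


def run_all_strategies(ps: ParameterSet, lt: LifeTable) -> dict[str, StrategyResult]:
    """One-time results for the reference and both active strategies."""
    return {s.value: run_strategy(ps, lt, s) for s in STRATEGIES}


def canonical_parameter_set() -> ParameterSet:
    """The seed-0 synthetic parameter registry shipped with the package."""
    ref = resources.files("t2dcea").joinpath("data/canonical_params.yaml")
    with resources.as_file(ref) as path:
        return load_parameters(path)


def canonical_life_table() -> LifeTable:
    from .synthetic_data import GeneratorConfig, make_life_table

    return make_life_table(GeneratorConfig())
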