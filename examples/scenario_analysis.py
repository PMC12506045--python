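"""Scenario analyses: repeated rescreening, adherence grid, knowledge search.

1. Rescreening over the first 10 years (annual for pre-diabetes, moderate
   and high-risk tiers and flagged false negatives; every 3 years for the
   low-risk tier; 6% participation per event).
2. The minimum referral-adherence level at which one-time screening is
   cost-effective at 1x GDP per capita.
3. The smallest education-induced knowledge gain that makes the combined
   strategy cost-saving outright.
"""

import numpy as np

from t2dcea import canonical_life_table, canonical_parameter_set, incremental, run_strategy
from t2dcea.scenarios import (
    RescreenSchedule,
    grid_minimum,
    knowledge_gain_for_cost_saving,
    run_repeated,
)

ps = canonical_parameter_set()
lt = canonical_life_table()
gdp = ps["wtp_gdp_per_capita"]
ref = run_strategy(ps, lt, "reference")

sched = RescreenSchedule.from_parameters(ps)
for strat in ("screening", "screening_education"):
    one = run_strategy(ps, lt, strat)
    rep = run_repeated(ps, sched, strat, lt)
    print(f"{strat}: one-time ICER {incremental(ref, one).icer:,.0f}, "
          f"repeated ICER {incremental(ref, rep).icer:,.0f} Int$/QALY")
print("Repeating screening finds more cases but at a higher price per QALY,")
print("because each round costs kits and worker incentives while detection")
print("yields diminish.\n")

grid = np.round(np.arange(0.05, 1.0001, 0.05), 2)
table, minimum = grid_minimum(ps, lt, "adherence", threshold=gdp, grid=grid)
print(f"minimum referral adherence for cost-effectiveness at 1xGDP: {minimum}")

dk = knowledge_gain_for_cost_saving(ps, lt, step=0.1)
print(f"knowledge gain needed for the education strategy to be cost-saving: "
      f"{dk} points (observed matched effect: {ps['atet_knowledge']} points)")
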