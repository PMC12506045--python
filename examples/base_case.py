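"""Deterministic base case: one-time screening strategies vs no intervention.

Loads the canonical synthetic parameter registry (cohort of 1183 persons
aged 40, 10.7% screening uptake, 6.0% referral adherence, 3% discounting),
runs the decision tree + lifetime Markov model for the three strategies and
prints the cost-effectiveness table.  ICERs are Int$ per QALY gained; a
strategy is conventionally cost-effective below 1x GDP per capita
(Int$14 445.7).
"""

from t2dcea import (
    canonical_life_table,
    canonical_parameter_set,
    compare_to_threshold,
    incremental,
    make_report,
    run_all_strategies,
)

ps = canonical_parameter_set()
lt = canonical_life_table()

results = run_all_strategies(ps, lt)
table = make_report(results, reference="reference")
print(table.round(2).to_string())
print()
for name in ("screening", "screening_education"):
    ce = incremental(results["reference"], results[name])
    verdict = compare_to_threshold(ce, ps["wtp_gdp_per_capita"]).value
    print(f"{name}: ICER = {ce.icer:,.0f} Int$/QALY -> {verdict}")
print()
print("Interpretation: both one-time strategies buy additional QALYs at a")
print("price per QALY below one GDP per capita on the synthetic inputs; the")
print("education arm is the more efficient because averted disease offsets")
print("part of its extra programme cost.")
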