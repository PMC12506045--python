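# t2dcea

Health-economic modelling of **community-based type 2 diabetes (T2D)
screening and health education** in an Indonesia-like setting, built for
health-economics researchers and modellers who want a tested, scriptable
implementation of the full analysis rather than a spreadsheet.

Community health workers offer adults aged 40+ a random capillary blood
glucose (RCBG) test and a non-communicable-disease risk triage (BMI, waist
circumference, blood pressure, glucose), with or without structured health
education; probable or high-risk cases are referred to primary healthcare
(PHC) for confirmation and treatment. The package asks the policy question:
*given realistic uptake and referral adherence, is this worth paying for?*

## The model

A **decision tree** routes a closed cohort (N = 1183, age 40, no prior
diabetes diagnosis) through attendance (uptake 10.7%), test accuracy
(Se/Sp), risk triage, referral and adherence (6.0%) into seven clinical end
groups stratified by education exposure. A **lifetime Markov cohort model**
(1-year cycles, eight health states: three NGT risk tiers, pre-diabetes,
undiagnosed T2D, diagnosed T2D, CVD, death) projects costs and QALYs until
cohort extinction, with age-specific all-cause mortality applied first and
an elevated cardiovascular hazard for undiagnosed diabetes,
`p = 1 − (1 − p₀)^HR`. Costs and effects are discounted at 3% per year.

Strategies are compared pairwise against no intervention via

```
ICER = ΔC / ΔE        NMB(λ) = λ·ΔE − ΔC        CEAC(λ) = P(NMB(λ) > 0)
```

with willingness-to-pay thresholds of 1–3× GDP per capita
(Int$14 445.7). The probabilistic base case re-runs the whole pipeline on
10 000 Monte-Carlo parameter draws under common random numbers; one-way
sensitivity pins single parameters to their bounds over the same stored
draw set. Scenario analyses cover repeated rescreening over a 10-year
window, uptake/adherence grids, and the knowledge gain needed for the
education arm to become cost-saving. The education effect itself — a
knowledge-score gain estimated by **propensity-score matching** (ATET
0.860, SE 0.250) — maps through a behaviours-per-knowledge-point
coefficient to a relative-risk multiplier on pre-diabetes/T2D incidence.

The study that motivates the model publishes its design constants but not
its full parameter tables; the `synthetic_data` module generates a
complete, validated stand-in registry in which every unpublished value is a
documented plausible placeholder tagged `synthetic` (see
`docs/methods.md`). Results on the canonical synthetic set reproduce the
qualitative published pattern, not its exact numbers.

## Worked example

```
python examples/base_case.py
```

prints, on the canonical synthetic inputs:

```
                   reference   screening  screening_education
cbhi_cost               0.00     1253.16              6253.16
treatment_cost    1279999.59  1280519.95           1278090.18
total_cost        1279999.59  1281773.11           1284343.34
total_qaly          21269.87    21270.31             21271.59
incremental_cost         NaN     1773.53              4343.75
incremental_qaly         NaN        0.44                 1.72
icer                     NaN     4065.26              2524.32

screening: ICER = 4,065 Int$/QALY -> ce_at_1gdp
screening_education: ICER = 2,524 Int$/QALY -> ce_at_1gdp
```

Reading: one-time screening buys 0.44 extra discounted QALYs for
Int$1 774 over the cohort's lifetime (Int$4 065 per QALY); adding health
education costs more in programme terms but averts enough disease to
reach Int$2 524 per QALY. Both fall below one GDP per capita, the
conventional cost-effectiveness bar. The other examples
(`probabilistic_analysis.py`, `one_way_sensitivity.py`,
`scenario_analysis.py`, `education_effect_psm.py`) each exercise one
capability and print a short interpretation.

## Layout

```
src/t2dcea/
  params.py          parameter registry, distributions, validation, I/O
  screening_tree.py  decision-tree cascade and risk triage
  markov_engine.py   state space, transition matrices, lifetime projection
  education.py       knowledge -> lifestyle -> incidence-risk linkage
  economics.py       ICER / NMB / dominance / reporting
  uncertainty.py     PSA draws, CEAC, one-way sensitivity, tornado
  scenarios.py       rescreening schedules, grids, knowledge-gain search
  psm.py             propensity-score matching ATET estimator
  synthetic_data.py  parameter-set, survey and life-table generators
  validation.py      independent oracles (enumeration, microsimulation)
  data/              canonical seed-0 parameter registry (YAML)
```
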