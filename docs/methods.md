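# Methods

This note records the model as implemented: its structure, assumptions,
parameters, numerical conventions, the synthetic inputs, and the open
design choices with the reasoning behind them. It states no result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Model structure

The analysis is a hybrid of a short-term decision tree and a long-term
Markov cohort model, evaluated in expectation (fractional persons) from a
payer perspective.

**Decision tree.** A closed cohort of `cohort_size` persons aged
`start_age` with no prior diabetes diagnosis is offered one round of
community screening. A fraction `uptake` attends and is split across five
glycaemic strata by `prevalence` (undiagnosed T2D, pre-diabetes, and
low/moderate/high-risk normal glucose tolerance). Diabetic attendees test
positive with probability `rcbg_sensitivity`; non-diabetic attendees with
`1 − rcbg_specificity`. High-risk (red-triage) attendees are referred
regardless of the glucose result; all referred persons follow up with
probability `referral_adherence`. Adherent true positives are diagnosed
and treated at primary care; adherent false positives are confirmed
non-diabetic and return to their tier; adherent high-risk persons enrol in
primary-care risk management. Non-attendees, refusers and false negatives
keep their underlying state, with unconfirmed diabetes remaining
undiagnosed — the no-intervention reference allocates the whole cohort
this way. Under the education strategy every attendee also enters the
educated stratum.

Risk triage follows per-indicator green/yellow/red cut-offs (BMI 23 /
25 kg/m²; waist > 90 cm men / > 80 cm women; BP 130/80 and 140/90 mmHg;
glucose 145 and 200 mg/dL) with a worst-indicator-wins aggregation, since
only per-indicator cut-offs are published; glucose ≥ 200 mg/dL always
triggers referral.

**Markov model.** Eight health states — NGT low/moderate/high risk,
pre-diabetes, undiagnosed T2D, diagnosed T2D, cardiovascular disease
(CVD), dead — crossed with modifier strata that are not disease states:
education exposure, primary-care risk management (Prolanis), diagnosis
setting (primary vs secondary care), and a "flagged" marker for
screen-missed diabetes known to the programme. This keeps the state count
faithful while letting strata scale costs, utilities and transition
intensities. Annual cycles run until the whole cohort is dead (an
`age_cap` of 110 with certain death guarantees termination).

Competing risks compose **mortality-first**: each live state sends
`qx(age)` to death; the CVD state adds case fatality as
`1 − (1 − qx)(1 − cf)`; survivors are then redistributed by the
age-independent conditional transition matrix. The published description
does not fix an ordering; mortality-first is the common convention and
makes the all-cause and disease-specific components separable. The
undiagnosed state's CVD probability is elevated on the complementary-log
scale, `1 − (1 − p)^HR`, the standard conversion for annual probabilities
under proportional hazards. Pre-diabetes progresses to *undiagnosed* T2D
unless the compartment is under risk management, in which case incident
diabetes is assumed caught at once and treated at primary care; diabetes
detected outside screening surfaces at secondary (specialist) care with
its own, higher cost and lower utility — the implementation keeps both the
cost and the utility distinct per setting, configurably.

**Accrual and discounting.** Per-cycle costs and QALYs are evaluated on
end-of-cycle occupancy with no half-cycle correction (none is described
for the source analysis; the convention is explicit in the code and
symmetric across strategies, so incrementals are insensitive to it).
Cycle-t amounts are discounted by `(1+r)^−t` at `discount_rate` = 3%; the
tree phase (t = 0) is undiscounted. Programme costs comprise community
health worker training and first-year incentives, glucose-test kits per
person screened, and education-material development for the education arm.

## Education effect

Health education raises the diabetes-knowledge score (18-point scale). The
expected number of newly adopted healthy behaviours is
`b = min(1, β · Δk)` with `β = beta_knowledge_to_lifestyle` (behaviours
per point); the incidence multiplier `1 − b · rr_lifestyle` scales the
annual probabilities of developing pre-diabetes *and* T2D in the educated
stratum, for the remaining lifetime (no decay — the published account is
silent on effect duration, and a conservative alternative can be obtained
by setting the multiplier back to 1 after any cycle). The default
**fractional** linkage (with the one-behaviour cap) is preferred over a
hard threshold because the base-case gain of 0.86 points is well below the
~3.4 points that guarantee a behaviour change, yet the education arm is
reported beneficial at base case; a pure threshold at 0.86 would
contradict that, while the cap still honours the one-behaviour evidence.
β defaults to 0.294 ≈ 1/3.4, so a 3.4-point gain corresponds to exactly
one adopted behaviour. The knowledge gain itself is the
propensity-score-matched ATET (0.860, SE 0.250) and enters as a
parameter; the regression linking knowledge to lifestyle is an input
coefficient, not re-estimated here.

## Propensity-score matching

The ATET estimator is 1:1 nearest-neighbour matching **with replacement**
on the logit of the propensity score, caliper 0.2 SD of the logit score —
the standard default, as the published text does not specify the matching
variant. The propensity model is a maximum-likelihood logistic regression
(statsmodels) of participation on covariates, with collinear columns
dropped by QR rank detection and a fatal error on perfect separation. The
standard error bootstraps the *entire* fit–match–estimate pipeline (999
replicates by default; percentile 95% CI), which honestly reflects the
resampling distribution of the whole procedure rather than only the final
mean difference. Standardised mean differences before/after matching are
reported as balance diagnostics.

## Uncertainty analysis

Distribution families follow the conventional assignments: beta for
probabilities, prevalence and utilities (method of moments,
`α = m·ν, β = (1−m)·ν, ν = m(1−m)/s² − 1`, with a fatal error when the
moments are infeasible); gamma for costs (`shape = m²/s²`,
`scale = s²/m`); normal for test accuracy and the knowledge effect,
truncated to the parameter's admissible range so draws of probabilities
stay in [0, 1]; lognormal for hazard/risk ratios. A CI-specified lognormal
uses `μ = ln m`, `σ = (ln hi − ln lo)/(2·1.96)`; an SE-specified one is
moment-matched (`σ² = ln(1 + s²/m²)`, `μ = ln m − σ²/2`) so the sample
mean reproduces the base value. Prevalence components are drawn jointly
and renormalised to the simplex. Joint draws that would break a model
invariant (e.g. outgoing transition mass above 1) are rejected and
redrawn, with the count required to stay under 1% of iterations.

The probabilistic base case uses 10 000 iterations with **common random
numbers**: every strategy, every one-way sensitivity run and every
scenario re-uses the same stored draw matrix, so differences between
configurations cannot come from sampling noise. One-way sensitivity pins
one parameter to its bound — its declared 95% CI when present, otherwise
±30% of base (clipped to [0, 1] for probabilities/utilities) — across all
iterations and recomputes the expected incremental result; the CEAC grid
spans 0 to 3× GDP per capita in 1% steps. Negative draws of the knowledge
gain are truncated at zero (education cannot do harm through ignorance in
this model).

## Scenarios

**Repeated rescreening.** During cycles 1..10, current pre-diabetes,
moderate-risk and unmanaged high-risk compartments (plus flagged false
negatives) are rescreened annually and the low-risk tier every third year,
at 6% participation per event. Detected diabetes moves to primary-care
treatment, detected high risk enrols in management. Eligibility is
resolved by *current* Markov state at each event; the published narrative
assigns rescreening groups by initial classification and is silent on
people whose state changes later, and current-state eligibility is both
implementable without extra bookkeeping and epidemiologically sensible (a
person who has progressed is screened as what they now are). By default
participation and referral adherence remain two multiplicative hurdles
(screen-positive persons must still follow the referral); a switch
collapses them, since the published wording is ambiguous. Each event
accrues kit costs per person screened; yearly worker incentives accrue in
window years in which screening actually happens, which makes a zeroed
schedule reproduce the one-time strategy bit-exactly (a property the test
suite relies on). Whether re-detected persons' management costs persist
beyond the window: they do (lifetime), matching the one-time arm's
convention.

**Grids and search.** The uptake/adherence grids evaluate the strategy at
each level from 5% to 100% with everything else at base, and report the
smallest level meeting the threshold. The knowledge-gain search scans
0..18 points and returns the smallest gain at which the education
strategy's total cost falls below the reference's.

## Synthetic inputs

The source study prints its design constants (cohort 1183 aged 40, uptake
10.7%, adherence 6.0%, discount 3%, ATET 0.860/SE 0.250 on an 18-point
scale, GDP per capita Int$14 445.7, IDR 4850.70 per Int$, 10 000
iterations, 10-year rescreen window) but keeps transition probabilities,
utilities, state costs, test accuracy and prevalence in unpublished
supplementary material. The generator therefore emits those as
**documented plausible placeholders** for an Indonesia-like cohort aged
40, each tagged `synthetic` so reports can never pass them off as
published values. The placeholder magnitudes (e.g. ~5% undiagnosed-T2D
prevalence at entry, annual pre-diabetes→T2D progression 3.5%, CVD hazard
ratio 1.8 for undiagnosed diabetes, Int$350/550 annual treatment cost at
primary/secondary care, Int$1 000 for CVD) were chosen once for public
plausibility and so that the *qualitative* published ordering holds on the
canonical set: education costs more than screening-only, repeated costs
more than one-time, ICERs rank education < screening-only and one-time <
repeated, and the education arm becomes cost-saving only at a knowledge
gain of a few points. Non-zero seeds jitter the placeholders by ±5% to
explore a family of neighbouring models in property sweeps; seed 0 ships
as the canonical fixture (`src/t2dcea/data/canonical_params.yaml`).

The life table is Gompertz, `qx = min(1, a·e^{b(age−40)})` with
`a = 2.5×10⁻³`, `b = 0.092`, closed at 110 — about 33.8 years of life
expectancy at 40, in the plausible range for the setting. The survey
generator plants a knowledge effect of 0.860 points on a confounded
participation model (logistic in age, sex, education, urbanicity,
wealth), n = 1018 with control mean 8.930, mirroring the published
matched-sample dimensions; its manifest records the ground truth for
recovery tests.

What the synthetic inputs deliberately do **not** emulate: correlation
between triage risk category and glycaemic state beyond the prevalence
strata (no joint distribution is published); microvascular complications
(CVD proxies all diabetes complications); societal costs; community-level
spillover of education; and any calibration to the published table's
exact totals (an under-determined inverse problem). Passing tests
therefore certify the machinery — conservation, oracle agreement,
estimator recovery, reproducibility — on a plausible model of this class,
not the published point estimates.

## Numerical conventions and problem sizes

- Conservation tolerances: 1e−6 persons on tree and trace rows; ICER
  identity to 1e−6; effect differences below 1e−12 count as zero effect.
- Terminations: extinction threshold `N·(1 − 1e−9)` dead or age 110.
- Reproducibility: every stochastic component (draws, microsimulation,
  matching tie-breaks, bootstrap, generators) takes an explicit seed;
  identical seeds give bit-identical results.
- The test suite and acceptance script size their stochastic checks to
  run comfortably on one CPU: the microsimulation oracle uses 200 000
  head-count walkers in 20 batches (comparison within 3 Monte-Carlo SEs
  of a digest of state occupancies and discounted totals); the
  probabilistic base case in the acceptance script uses the full 10 000
  iterations, while unit tests use 40–200; the matching-recovery
  experiment uses 50 survey replicates with 99–199 bootstrap draws
  (the library default remains 999).
- Degenerate inputs are fatal with named messages: infeasible beta/gamma
  moments, transition mass above 1 (naming the compartment), missing
  configuration keys, empty grids, calipers with no eligible controls.

## Known limitations

- The Markov engine is specific to this disease model's state space; it is
  not a general multi-state engine.
- One-way sensitivity re-evaluates the full pipeline over the stored draw
  set per parameter bound, which is exact but slow for long parameter
  lists; pass a smaller draw subset for exploratory tornado plots.
- The bootstrap SE ignores clustering in the survey design (none is
  modelled by the generator).
- With fractional linkage and the one-behaviour cap, education effects
  above `1/β` points are indistinguishable; scenario searches respect the
  cap by construction.
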