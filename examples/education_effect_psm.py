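"""Estimating the health-education effect by propensity-score matching.

Generates synthetic community-survey microdata with a planted 0.86-point
knowledge-score treatment effect and confounded programme participation,
then estimates the average treatment effect on the treated (ATET): logistic
propensity model, 1:1 nearest-neighbour matching with replacement within a
0.2-SD logit caliper, and a bootstrap of the whole pipeline for the
standard error.
"""

from t2dcea.psm import atet_pipeline, balance_table, fit_propensity, match_treated
from t2dcea.synthetic_data import GeneratorConfig, make_survey

COVARIATES = ["age", "female", "edu_years", "urban", "wealth"]

g = GeneratorConfig(seed=1)
survey = make_survey(g)
print(f"survey: n={len(survey)}, treated={int(survey.treated.sum())}, "
      f"planted ATET={g.atet}")

est = atet_pipeline(survey, COVARIATES, n_boot=199, seed=1)
print(f"ATET = {est.atet:.3f} (SE {est.se:.3f}), "
      f"95% CI [{est.ci_low:.3f}, {est.ci_high:.3f}]")
print(f"matched {est.n_matched}/{est.n_treated} treated "
      f"({100 * est.unmatched_fraction:.1f}% unmatched)")

scores = fit_propensity(survey, COVARIATES)
m = match_treated(scores, survey["treated"].to_numpy(), seed=1)
print("\ncovariate balance (standardised mean differences):")
print(balance_table(survey, COVARIATES, m).round(3).to_string())
print()
print("Matching removes the participation confounding: post-match SMDs sit")
print("near zero and the estimate brackets the planted knowledge gain,")
print("which feeds the model's education risk multiplier.")
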