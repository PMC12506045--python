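linkage_mode: fractional
parameters:
  cohort_size:
    value: 1183.0
    kind: count
    provenance: paper
    family: fixed
    description: 'hypothetical cohort: persons aged 40 served by one community unit'
  start_age:
    value: 40.0
    kind: count
    provenance: paper
    family: fixed
  cycle_length:
    value: 1.0
    kind: count
    provenance: paper
    family: fixed
  discount_rate:
    value: 0.03
    kind: rate
    provenance: paper
    family: fixed
    description: annual discount rate applied to costs and effects
  uptake:
    value: 0.107
    kind: probability
    provenance: paper
    family: beta
    se: 0.02
    description: fraction of the eligible cohort attending community screening
  referral_adherence:
    value: 0.06
    kind: probability
    provenance: paper
    family: beta
    se: 0.015
    description: fraction of referred attendees following up at primary care
  rescreen_adherence:
    value: 0.06
    kind: probability
    provenance: paper
    family: beta
    se: 0.015
    description: participation in scheduled rescreening (set equal to referral adherence)
  atet_knowledge:
    value: 0.86
    kind: rate
    provenance: paper
    family: normal
    se: 0.25
    description: matched knowledge-score gain from health education (points)
  knowledge_scale_max_gain:
    value: 18.0
    kind: count
    provenance: paper
    family: fixed
  wtp_gdp_per_capita:
    value: 14445.7
    kind: cost
    provenance: paper
    family: fixed
    description: Indonesia GDP per capita 2022, Int$
  fx_idr_per_intd:
    value: 4850.7
    kind: rate
    provenance: paper
    family: fixed
    description: IDR per international dollar, 2022
  mcs_iterations:
    value: 10000.0
    kind: count
    provenance: paper
    family: fixed
  owsa_default_range:
    value: 0.3
    kind: rate
    provenance: paper
    family: fixed
  rescreen_window:
    value: 10.0
    kind: count
    provenance: paper
    family: fixed
  age_cap:
    value: 110.0
    kind: count
    provenance: user
    family: fixed
  rcbg_sensitivity:
    value: 0.75
    kind: probability
    provenance: synthetic
    family: normal
    se: 0.04
  rcbg_specificity:
    value: 0.88
    kind: probability
    provenance: synthetic
    family: normal
    se: 0.03
  prev_t2d_undiagnosed:
    value: 0.04999999999999999
    kind: probability
    provenance: synthetic
    family: beta
    se: 0.01
  prev_prediabetes:
    value: 0.09999999999999998
    kind: probability
    provenance: synthetic
    family: beta
    se: 0.02
  prev_ngt_low:
    value: 0.5499999999999999
    kind: probability
    provenance: synthetic
    family: beta
    se: 0.05
  prev_ngt_mod:
    value: 0.19999999999999996
    kind: probability
    provenance: synthetic
    family: beta
    se: 0.03
  prev_ngt_high:
    value: 0.09999999999999998
    kind: probability
    provenance: synthetic
    family: beta
    se: 0.02
  tp_ngt_low_to_mod:
    value: 0.03
    kind: probability
    provenance: synthetic
    family: beta
    se: 0.008
  tp_ngt_mod_to_high:
    value: 0.03
    kind: probability
    provenance: synthetic
    family: beta
    se: 0.008
  tp_ngt_low_to_pre:
    value: 0.006
    kind: probability
    provenance: synthetic
    family: beta
    se: 0.002
  tp_ngt_mod_to_pre:
    value: 0.015
    kind: probability
    provenance: synthetic
    family: beta
    se: 0.004
  tp_ngt_high_to_pre:
    value: 0.04
    kind: probability
    provenance: synthetic
    family: beta
    se: 0.01
  tp_pre_to_t2d:
    value: 0.035
    kind: probability
    provenance: synthetic
    family: beta
    se: 0.009
  tp_undiag_detection:
    value: 0.1
    kind: probability
    provenance: synthetic
    family: beta
    se: 0.025
  tp_t2d_to_cvd:
    value: 0.02
    kind: probability
    provenance: synthetic
    family: beta
    se: 0.005
  tp_cvd_case_fatality:
    value: 0.05
    kind: probability
    provenance: synthetic
    family: beta
    se: 0.012
  hr_cvd_undiagnosed:
    value: 1.8
    kind: ratio
    provenance: synthetic
    family: lognormal
    se: 0.25
  rr_prolanis_management:
    value: 0.7
    kind: ratio
    provenance: synthetic
    family: lognormal
    se: 0.08
  u_ngt:
    value: 0.92
    kind: utility
    provenance: synthetic
    family: beta
    se: 0.015
  u_prediabetes:
    value: 0.9
    kind: utility
    provenance: synthetic
    family: beta
    se: 0.015
  u_t2d_undiagnosed:
    value: 0.88
    kind: utility
    provenance: synthetic
    family: beta
    se: 0.02
  u_t2d_phc:
    value: 0.82
    kind: utility
    provenance: synthetic
    family: beta
    se: 0.02
  u_t2d_secondary:
    value: 0.76
    kind: utility
    provenance: synthetic
    family: beta
    se: 0.025
  u_cvd:
    value: 0.65
    kind: utility
    provenance: synthetic
    family: beta
    se: 0.03
  c_t2d_phc:
    value: 350.0
    kind: cost
    provenance: synthetic
    family: gamma
    se: 60.0
  c_t2d_secondary:
    value: 550.0
    kind: cost
    provenance: synthetic
    family: gamma
    se: 90.0
  c_cvd:
    value: 1000.0
    kind: cost
    provenance: synthetic
    family: gamma
    se: 180.0
  c_prolanis_highrisk:
    value: 60.0
    kind: cost
    provenance: synthetic
    family: gamma
    se: 12.0
  pc_chw_training:
    value: 400.0
    kind: cost
    provenance: synthetic
    family: gamma
    se: 60.0
  pc_chw_incentives_yearly:
    value: 600.0
    kind: cost
    provenance: synthetic
    family: gamma
    se: 80.0
  pc_education_materials:
    value: 5000.0
    kind: cost
    provenance: synthetic
    family: gamma
    se: 700.0
  pc_rcbg_kit:
    value: 2.0
    kind: cost
    provenance: synthetic
    family: gamma
    se: 0.4
  beta_knowledge_to_lifestyle:
    value: 0.294
    kind: rate
    provenance: synthetic
    family: normal
    se: 0.05
  rr_lifestyle:
    value: 0.1
    kind: probability
    provenance: synthetic
    family: beta
    se: 0.03
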