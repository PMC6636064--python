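# Default synthetic-cohort configuration, version 1.
#
# Marginal moments, category frequencies, prevalences and recorded fractions are
# calibrated to the baseline characteristics of a large English primary-care CVD
# cohort (two-sex, ages 25-84, index dates 1998-2015).  Log hazard ratios are
# round QRISK-scale effects; the secular trend is HR 0.96 per calendar year and
# region intercepts have SD ~0.085 on the log-hazard scale.
version: 1
study:
  start_date: "1998-01-01"
  end_date: "2015-12-31"
  reference_year: 1998.0
  age_range: [25.0, 84.0]

baseline_hazard:            # Weibull: H0(t) = (t / scale)^shape, t in years
  F: {shape: 1.0, scale: 309.0}
  M: {shape: 1.0, scale: 229.0}

trend_loghr: -0.0408219945202551   # log(0.96) per calendar year
region_effect_sd: 0.085
dropout_rate: 0.04                 # exponential loss to follow-up, per year
sex_fraction_female: 0.51

continuous:                 # mean/sd are marginal; slope_age shifts the mean per year of age
  age:
    F: {mean: 43.07, sd: 15.94}
    M: {mean: 41.84, sd: 14.57}
  bmi:
    F: {mean: 25.60, sd: 5.60, slope_age: 0.06, lo: 14.0, hi: 65.0}
    M: {mean: 26.12, sd: 4.54, slope_age: 0.05, lo: 14.0, hi: 65.0}
  sbp:
    F: {mean: 123.91, sd: 18.28, slope_age: 0.45, lo: 70.0, hi: 230.0}
    M: {mean: 130.03, sd: 16.48, slope_age: 0.35, lo: 70.0, hi: 230.0}
  sbp_variability:
    F: {mean: 9.47, sd: 5.98, slope_age: 0.08, lo: 0.1, hi: 60.0}
    M: {mean: 10.13, sd: 6.80, slope_age: 0.08, lo: 0.1, hi: 60.0}
  chol_hdl:
    F: {mean: 3.72, sd: 1.20, slope_age: 0.012, lo: 1.0, hi: 12.0}
    M: {mean: 4.48, sd: 1.40, slope_age: 0.012, lo: 1.0, hi: 12.0}

smoking:
  levels: [never, ex, current]
  F: [0.5604, 0.1697, 0.2699]
  M: [0.4663, 0.1748, 0.3599]

ethnicity:
  levels: [white, indian, pakistani, bangladeshi, other_asian, black, chinese, other]
  F: [0.9410, 0.0114, 0.0045, 0.0014, 0.0084, 0.0173, 0.0033, 0.0127]
  M: [0.9448, 0.0119, 0.0049, 0.0019, 0.0078, 0.0152, 0.0023, 0.0112]

region:
  levels: [north_east, north_west, yorkshire_humber, east_midlands, west_midlands,
           east_of_england, south_west, south_central, london, south_east_coast]
  F: [0.0189, 0.1310, 0.0393, 0.0314, 0.1104, 0.1167, 0.1199, 0.1284, 0.1752, 0.1288]
  M: [0.0196, 0.1338, 0.0385, 0.0323, 0.1128, 0.1168, 0.1188, 0.1281, 0.1718, 0.1274]

flags:                      # prevalence per sex; erectile dysfunction is male-only
  atrial_fibrillation:      {F: 0.0044, M: 0.0057}
  atypical_antipsychotic:   {F: 0.0030, M: 0.0033}
  ckd345:                   {F: 0.0045, M: 0.0032}
  ckd45:                    {F: 0.0012, M: 0.0015}   # nested inside ckd345
  corticosteroid:           {F: 0.0048, M: 0.0030}
  erectile_dysfunction:     {F: 0.0,    M: 0.0145}
  family_history_cvd:       {F: 0.1508, M: 0.1102}
  hiv_aids:                 {F: 0.0006, M: 0.0009}
  migraine:                 {F: 0.0727, M: 0.0294}
  rheumatoid_arthritis:     {F: 0.0069, M: 0.0026}
  severe_mental_illness:    {F: 0.0863, M: 0.0459}
  sle:                      {F: 0.0010, M: 0.0001}
  treated_hypertension:     {F: 0.0618, M: 0.0450}
  type1_diabetes:           {F: 0.0021, M: 0.0028}
  type2_diabetes:           {F: 0.0116, M: 0.0142}
  alcohol_abuse:            {F: 0.0065, M: 0.0146}
  anxiety:                  {F: 0.1344, M: 0.0796}
  lvh:                      {F: 0.0014, M: 0.0018}

counts:                     # negative binomial (mean, dispersion r); dichotomised at >50
  consult_count:
    F: {mean: 14.94, r: 1.2}
    M: {mean: 8.83,  r: 1.0}
  rx_count:
    F: {mean: 9.60, r: 0.5}
    M: {mean: 5.72, r: 0.45}

loghr:                      # log hazard ratios; continuous effects are per unit, centred
  age: {value: 0.075, center: 45.0}
  bmi: {value: 0.02, center: 26.0}
  sbp: {value: 0.011, center: 125.0}
  sbp_variability: {value: 0.02, center: 10.0}
  chol_hdl: {value: 0.13, center: 4.0}
  townsend: {value: 0.08, center: 3.0}
  smoking: {never: 0.0, ex: 0.20, current: 0.55}
  ethnicity: {white: 0.0, indian: 0.25, pakistani: 0.45, bangladeshi: 0.55,
              other_asian: 0.20, black: -0.05, chinese: -0.25, other: 0.0}
  flags:
    atrial_fibrillation: 0.90
    atypical_antipsychotic: 0.15
    ckd345: 0.35
    ckd45: 0.60
    corticosteroid: 0.40
    erectile_dysfunction: 0.15
    family_history_cvd: 0.45
    hiv_aids: 0.30
    migraine: 0.25
    rheumatoid_arthritis: 0.25
    severe_mental_illness: 0.12
    sle: 0.50
    treated_hypertension: 0.55
    type1_diabetes: 1.20
    type2_diabetes: 0.75
    alcohol_abuse: 0.30
    anxiety: 0.095
    lvh: 0.50
  consult_gt50: 0.26
  rx_gt50: 0.44

missingness:                # target recorded fractions; MAR logistic slope on age per decade
  age_slope_per_decade: -0.4
  recorded:
    bmi:             {F: 0.6883, M: 0.5362}
    sbp:             {F: 0.8101, M: 0.5921}
    sbp_variability: {F: 0.5039, M: 0.2094}
    chol_hdl:        {F: 0.3848, M: 0.3571}
    smoking:         {F: 0.7518, M: 0.6517}
    ethnicity:       {F: 0.4207, M: 0.3821}

prescriptions:
  initiation_prob: 0.12     # probability a patient ever starts a statin
  gap_mean_days: 45.0       # exponential gap between successive prescriptions
  max_per_patient: 200
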