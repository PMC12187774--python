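# Study configuration: synthetic cohort emulating the cystectomy registry,
# primary dichotomization line, adjustment set and desk-scale evaluation.
# Any block may be dropped to fall back to the packaged defaults.

synthetic:
  n_patients: 1482
  base_rate_beneficial: 0.783
  tifb_ne_coupling: -0.02
  noise_sd: 0.015
  covariate_spec:
    age: {kind: normal, mean: 68.0, sd: 10.0}
    bmi: {kind: normal, mean: 25.7, sd: 4.5}
    asa: {kind: ordinal, levels: [1, 2, 3, 4], probs: [0.021, 0.494, 0.460, 0.025]}
    charlson_index: {kind: normal, mean: 4.0, sd: 2.7}
    ckd_stage:
      kind: ordinal
      levels: [1, 2, 3, 4, 5]
      probs: [0.284, 0.410, 0.260, 0.036, 0.010]
    copd: {kind: binary, prevalence: 0.201}
    heart_disease: {kind: binary, prevalence: 0.312}
    hypertension: {kind: binary, prevalence: 0.510}
    statins: {kind: binary, prevalence: 0.233}
    year: {kind: uniform, low: 2000.0, high: 2020.5}
  confounding_coefs:
    intercept: -0.28
    year: -0.90
    ckd_stage: -0.30
    heart_disease: -0.25
    hypertension: -0.20
  outcome_coefs:
    age: -0.30
    bmi: -0.25
    asa: -0.25
    charlson_index: -0.30
    ckd_stage: -0.45
    heart_disease: -0.35
    hypertension: -0.40
    statins: -0.15
    year: -0.20
  effect_coefs:
    intercept: 1.9
    ckd_stage: 0.25
    heart_disease: 0.20
    hypertension: 0.20
    "heart_disease:hypertension": 2.6
    "ckd_stage:copd": 1.6

treatment:
  slope: 0.02
  offset: -0.04
  offset_grid: [-0.12, -0.08, -0.04, 0.0, 0.04, 0.08]
  adjustment_set: [year, ckd_stage, heart_disease, hypertension]
  multiplier: 10000
  clip_epsilon: 0.01

learners:
  logistic_regression: {C: 100.0}
  random_forest: {n_trees: 100}

experiment:
  n_bootstrap: 20
  n_pseudo_samples: 2
  n_cv_splits: 2
  train_fraction: 0.6
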