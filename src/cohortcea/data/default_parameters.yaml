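# Built-in base-case inputs; regenerate with cohortcea.params.dump_parameters(default_parameters()).
strategies:
  control:
    p_cv_death: 0.00975
    p_hosp: 0.02003
    p_readmit: 0.417
  empagliflozin:
    p_cv_death: 0.00864
    p_hosp: 0.01466
    p_readmit: 0.417
transition_matrix:
- - 0.977
  - 0.019
  - 0.004
  - 0.0
- - 0.008
  - 0.981
  - 0.01
  - 0.001
- - 0.0
  - 0.034
  - 0.96
  - 0.006
- - 0.0
  - 0.0
  - 0.055
  - 0.945
mortality:
  bands:
    65: 0.00243
    70: 0.003042
    75: 0.004185
utilities:
  nyha:
  - 0.825
  - 0.78
  - 0.65
  - 0.585
  hospitalization_disutility: -0.1
costs:
  standard_therapy_per_cycle: 131.96
  empagliflozin_per_cycle: 59.625
  hospitalization_per_event: 1783.39
cohort:
  start_age: 66.0
  horizon: 10.0
  cycle_length: 0.25
  initial_distribution:
  - 0.0
  - 0.81
  - 0.18
  - 0.01
  annual_discount_rate: 0.05
wtp_thresholds:
- 12652.5
- 37957.5
disutility_convention: absolute
distributions:
  p_cv_death.control:
    family: beta
    mean: 0.00975
    low: 0.00877
    high: 0.01072
  p_cv_death.empagliflozin:
    family: beta
    mean: 0.00864
    low: 0.00778
    high: 0.00951
  p_hosp.control:
    family: beta
    mean: 0.02003
    low: 0.01803
    high: 0.02204
  p_hosp.empagliflozin:
    family: beta
    mean: 0.01466
    low: 0.01319
    high: 0.01613
  p_readmit:
    family: beta
    mean: 0.417
    low: 0.3753
    high: 0.4587
  utility.nyha1:
    family: beta
    mean: 0.825
    low: 0.79
    high: 0.86
  utility.nyha2:
    family: beta
    mean: 0.78
    low: 0.75
    high: 0.81
  utility.nyha3:
    family: beta
    mean: 0.65
    low: 0.61
    high: 0.69
  utility.nyha4:
    family: beta
    mean: 0.585
    low: 0.51
    high: 0.66
  disutility.hospitalization:
    family: beta
    mean: 0.1
    low: 0.08
    high: 0.13
  cost.standard_therapy:
    family: gamma
    mean: 131.96
    low: 131.957
    high: 310.832
  cost.empagliflozin:
    family: gamma
    mean: 59.625
    low: 47.7
    high: 71.55
  cost.hospitalization:
    family: gamma
    mean: 1783.39
    low: 1029.73
    high: 3336.39
dirichlet_n_eff: 1000.0
sample_transition_matrix: true
yuan_per_usd: 6.4
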