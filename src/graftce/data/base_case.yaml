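# Base-case inputs: low-friction vs standard bedding after skin-graft surgery.
# Each parameter is a beta, lognormal, or point distribution; lognormals may
# instead be given as a median with a 95% interval, inverted on the log scale.
parameters:
  rr:
    family: lognormal
    median: 0.574
    ci: [0.52, 0.63]
    units: ratio
  p_regraft_lf:
    family: beta
    shape_a: 4.96
    shape_b: 125.04
    units: probability
  c_intervention:
    family: point
    value: 115
    units: GBP
  c_regraft:
    family: lognormal
    meanlog: 9.81
    sdlog: 0.35
    units: GBP
  c_no_regraft:
    family: lognormal
    meanlog: 9.20
    sdlog: 0.09
    units: GBP
  u_baseline:
    family: beta
    shape_a: 0.77
    shape_b: 1.41
    units: utility
  u_no_regraft:
    family: beta
    shape_a: 2.26
    shape_b: 2.19
    units: utility
  u_regraft:
    family: beta
    shape_a: 179.95
    shape_b: 106.82
    units: utility

model:
  horizon_days: 28
  days_per_year: 365.25
  wtp: 20000
  arms: [standard, low_friction]

population:
  annual_patients: 1000
  horizon_years: 10
  discount_rate: 0.035
  first_year_discounted: false

study:
  n_before: 131
  n_after: 90
  p_regraft_before: 0.06647
  p_regraft_after: 0.038154
  cost_logmean_regraft: 9.81
  cost_logsd_regraft: 0.35
  cost_logmean_no: 9.20
  cost_logsd_no: 0.09
  utility_baseline_ab: [0.77, 1.41]
  utility_no_ab: [2.26, 2.19]
  utility_re_ab: [179.95, 106.82]
  utility_completion_rate: 0.4444444444444444
  c_intervention: 115
  seed: 0
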