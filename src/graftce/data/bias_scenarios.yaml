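# Standard bias-scenario grid for the observational relative risk:
# median bias (none / favouring low-friction / against low-friction)
# crossed with high and low uncertainty, plus the face-value base case.
scenarios:
  - label: face_value
    median: 1.00
    ci: [1.00, 1.00]
    note: base case, evidence at face value
  - label: no_bias_high_uncertainty
    median: 1.00
    ci: [0.47, 1.88]
  - label: favour_lf_high_uncertainty
    median: 0.80
    ci: [0.29, 1.76]
  - label: against_lf_high_uncertainty
    median: 1.20
    ci: [0.65, 2.03]
  - label: no_bias_low_uncertainty
    median: 1.00
    ci: [0.74, 1.31]
  - label: favour_lf_low_uncertainty
    median: 0.80
    ci: [0.55, 1.13]
  - label: against_lf_low_uncertainty
    median: 1.20
    ci: [0.94, 1.51]
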