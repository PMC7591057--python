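cancer_label: generic-carcinoma
cohort:
  diameter_law:
    hi_cm: 15.0
    lo_cm: 0.2
    median_cm: 2.0
    sigma_log: 0.6
  follow_up_years: 25.0
  n_patients: 50000
  other_cause_hazard: 0.01
fit:
  detection_weight: 1.0
  generations: 150
  n_nodes: 192
  polish_maxfev: 2500
  quantile_weight: 1.0
  quantile_xtol: 0.0001
  quantiles:
  - 0.05
  - 0.14
  - 0.23
  - 0.32
  - 0.41
  - 0.5
  - 0.59
  - 0.68
  - 0.77
  - 0.86
  - 0.95
  restarts: 16
  seed: 0
  tol: 0.01
growth:
  cell_density: 1000000000.0
  doubling_time_days: 150.0
  extravasation_prob: 0.8
  initial_cells: 1.0
  shed_rate_at_1g: 150000.0
log_level: INFO
outcome:
  a: 1.0
  delta0: 6.0
  delta1: 5.5
  h: 1.0
  n_nodes: 256
  prior:
    kind: lognormal
    mu: 2.833213344056216
    sigma: 0.8
output_dir: out
seed: 7
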