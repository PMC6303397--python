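# Packaged end-to-end demo: a small synthetic study with a strong
# rejuvenation effect (kappa = 0.6, true tilt 0.4).
seed: 20180737
stages:
  expression: true
  survival: true
  gating: true
expression_sim:
  n_genes: 1500
  n_replicates_per_group: 4
  tissues: [kidney, liver, lung, skin]
  baseline_mean_log2: [6.0, 1.5]
  dispersion: 0.05
  frac_age_affected: 0.2
  age_effect_sd: 1.5
  rejuvenation_kappa: 0.6
  treatment_noise_sd: 0.3
  sasp_genes: 56
  sasp_age_up_bias: 0.8
survival_sim:
  groups:
    wildtype: {shape: 4.0, scale_days: 850.0}
    immune_deficient: {shape: 4.0, scale_days: 680.0}
  n_per_group: 30
  censor_time_days: 1100.0
cell_sim:
  n_cells: 20000
  senescent_fraction: 0.1
analysis:
  alpha: 0.05
  lfc_min: 0.0
  detection_threshold: 1.0
  pseudocount: 1.0
  conf_level: 0.95
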