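analytic_growth_cells: 16
angiogenesis:
  branch_prob_per_step: 0.0
  chemotaxis: 12.0
  chemotaxis_saturation: 1.0
  haptotaxis: 0.0
  max_active_tips: 150
  max_neovessel_segments: 4000
  min_fuse_age: 3
  motility: 1.0
  neovessel_radius_m: 1.0e-05
  sprout_rate_per_day: 2.5
  taf_decay: 10.0
  taf_diffusivity: 20.0
  taf_source: 10.0
  taf_threshold: 0.08
  tip_speed_mm_per_day: 0.45
drug:
  diffusivity_rel: 0.022
  half_life_h: 6.0
  reference_diffusivity: 20.0
drug_load_scale: 1000000000.0
dt_growth_days: 0.1
dt_treatment_h: 0.5
formulation:
  alpha_neo: 1000000000000.0
  beta: 0.0001
  delta1: 0.45
  delta2: 1.57
  diameter_m: 1.0e-07
  gamma: 10000.0
  n0: 10.0
grid:
  domain_size_mm: 2.0
  length_scale_mm: 0.2
  n_cells: 200
growth:
  chi_E: 0.0
  kill_cap_per_day: 48.0
  lam_apoptosis: 0.1
  lam_effect: 0.0
  lam_mitosis: 0.7
  lam_necrosis: 0.25
  mobility: 1.0
  sigma_H: 0.5
  sigma_N: 0.3
horizon_h: 72.0
injection_day: 18.0
injection_dt_s: 60.0
injection_duration_h: 1.0
oxygen:
  hematocrit_min: 0.25
  hematocrit_normal: 0.45
  k_pi: 0.95
  lam_ev: 10.0
  lam_necrosis: 0.35
  lam_tissue: 0.12
  lam_tumor: 2.5
  neovessel_hematocrit_fraction: 0.5
  p_e: 0.5
  q_s: 0.5
schema_version: 1
seed: 0
seed_radius_mm: 0.02
vessels:
  compression_depth: 1.0
  inlet_side: left
  max_compression: 0.5
  p_in_pa: 500.0
  p_out_pa: 0.0
  radius_m: 1.0e-05
  receptor_halo: 1.5
  spacing_mm: 0.25
  viscosity_pa_s: 0.003
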