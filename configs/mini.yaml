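# Two-sequence mini study: one plain paced sequence and one with a
# perfusion-bed analogue (slowed conduction + lengthened APD) facing the
# camera.  Runs in a few minutes on one CPU.
seed: 1

geometry:
  heart_semi_axes: [30.0, 30.0, 30.0]
  heart_center: [0.0, 0.0, 0.0]
  heart_edge_mm: 7.0
  tank_scale: [1.3, 1.3, 1.3]
  tank_edge_mm: 9.0
  n_sock: 64
  n_tank: 128

camera:
  direction: [0.0, -1.0, 0.0]
  distance_mm: 220.0
  init_perturb_mm: 10.0
  ref_jitter_px: 0.5

signals:
  elec_rate: 2000.0
  opt_rate: 1000.0
  egm_rho_mm: 8.0
  tank_noise_snr_db: 40.0
  optical_noise_snr_db: 30.0
  optical_blur_px: 1.0

scenario_defaults:
  pacing_cycle_ms: 500.0
  cv_base: 0.5
  apd_base: 200.0
  region_radius_mm: 15.0

sequences:
  - name: paced_plain
    pacing_point: [0.0, -21.0, 21.0]
  - name: paced_lad_cold
    pacing_point: [0.0, -21.0, 21.0]
    region_center_point: [0.0, -30.0, 0.0]
    region_radius_mm: 15.0
    cv_factor_region: 0.6
    apd_delta_region: 40.0

mfs:
  deflate: 0.8
  inflate: 1.2
  forward_factors: [0.7, 1.3]

markers:
  rt_window: [50.0, 450.0]
  gaf_max_lag_ms: 30.0
  gaf_cc_min: 0.5
  gaf_mu: 0.01

metrics:
  pairing_cutoff_px: 5.0
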