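task:
  n_context_rewards: 4
  context_duration_high: 5.0
  context_duration_low: 10.0
  travel_time: 0.3
  session_duration: 1080.0
  block_duration: 180.0
  n_blocks: 6
  hazard_bin: 0.1
  hazard_tau: 8.0
  hazard_p0: 0.09937759604894847
  expected_total_rewards: 8.0
policy:
  slope: -0.1
  intercept_high: 3.0
  intercept_low: 4.5
  baseline_wait: 4.0
  noise_sd: 0.3
  min_wait: 0.2
population:
  n_units: 16
  fraction_on_off: 0.25
  rate_low: 5.0
  rate_high: 20.0
  delay_min: 0.05
  delay_max: 0.95
  delay_jitter_sd: 0.05
  participation: 0.9
photometry:
  sampling_rate: 40.0
  kernel_rise: 0.07
  kernel_decay: 1.0
  peak_latency: 0.3
  amp_base: 0.05
  amp_nri_gain: 0.02
  amp_context_low_gain: 0.01
  amp_iri_suppression: 0.5
  iri_suppression_threshold: 1.0
  drift_amplitude: 5.0
  artifact_amplitude: 2.0
  noise_sd: 0.2
  baseline_470: 100.0
  baseline_405: 60.0
  drift_scale_405: 0.7
  amp_session_sd: 0.005
steps:
  rate_bin: 0.01
  slope_min: 11.0
  center_margin: 0.1
  center_slack: 0.1
  state_band: 0.2
  min_interval_duration: 0.3
  min_intervals: 10
  min_eligible: 5
  min_height: 3.0
  min_height_z: 3.0
  refine_step: true
  refine_window: 0.3
  n_center_starts: 1
n_sessions: 20
min_step_units: 6
svm_bin: 0.01
svm_leave_window: 5.0
hazard_bin: 0.25
seed: 1
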