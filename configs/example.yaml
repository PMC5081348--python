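n_subjects: 17
seed: 0
design:
  conditions:
  - small_left
  - small_right
  - large_left
  - large_right
  - mixed_left
  - mixed_right
  repeats_per_condition: 6
  block_duration_s: 4.0
  saccades_per_block: 6
  fixation_jitter_s:
  - 6.0
  - 8.0
  lead_trail_fixation_s: 8.0
  target_eccentricities_deg:
  - 5.0
  - 10.0
  - 30.0
  runs_per_subject: 5
  tr_s: 2.0
  target_jitter_frac: 0.3
  seed: 0
oculo:
  sampling_hz: 60.0
  latency_mean_s: 0.18
  latency_sd_s: 0.03
  latency_min_s: 0.08
  vmax_deg_s: 500.0
  a0_deg: 14.0
  endpoint_sd_slope: 0.02
  noise_sd_deg: 0.15
  blink_rate_hz: 0.0
  blink_duration_s: 0.2
  refixation_threshold_deg: 0.3
  corrective_threshold_deg: 0.5
  endpoint_max_sigmas: 2.0
  seed: 0
effects:
  mixed_rule: mean
  subject_gain_sd: 0.25
  rois:
    L-FEF:
      informative: true
      pattern_effect: 0.25
      common_effect: 1.0
      informative_fraction: 0.5
      adaptation_gain: 0.0
    R-FEF:
      informative: true
      pattern_effect: 0.25
      common_effect: 1.0
      informative_fraction: 0.5
      adaptation_gain: 0.0
    L-Prec:
      informative: false
      pattern_effect: 0.0
      common_effect: 1.0
      informative_fraction: 0.5
      adaptation_gain: 0.0
    R-Prec:
      informative: false
      pattern_effect: 0.0
      common_effect: 1.0
      informative_fraction: 0.5
      adaptation_gain: 0.0
    L-SEF:
      informative: false
      pattern_effect: 0.0
      common_effect: 1.0
      informative_fraction: 0.5
      adaptation_gain: 0.0
    R-SEF:
      informative: false
      pattern_effect: 0.0
      common_effect: 1.0
      informative_fraction: 0.5
      adaptation_gain: 0.0
    L-Par:
      informative: true
      pattern_effect: 0.4
      common_effect: 1.0
      informative_fraction: 0.5
      adaptation_gain: 0.0
    R-Par:
      informative: true
      pattern_effect: 0.4
      common_effect: 1.0
      informative_fraction: 0.5
      adaptation_gain: 0.0
noise:
  sd: 1.0
  ar1_rho: 0.3
  baseline: 100.0
  baseline_run_sd: 1.0
  drift_sd: 0.5
glm:
  highpass_sigma_s: 50.0
  include_temporal_derivatives: true
  n_motion_regressors: 6
  mode: per_block
  smoothing_fwhm_mm: 5.0
mvpa:
  svm_c: 1.0
  centering: both
  feature_min: 200
  feature_step: 100
  feature_cap: 900
  seed: 0
inference:
  alpha: 0.05
  n_permutations: 10000
  chance_pct: 50.0
  seed: 0
grid:
  voxel_size_mm:
  - 2.0
  - 2.0
  - 2.0
  origin_mm:
  - -64.0
  - -88.0
  - 20.0
  shape:
  - 64
  - 52
  - 28
  tr_s: 2.0
roi_sizes:
  L-FEF: 900
  R-FEF: 900
  L-Prec: 700
  R-Prec: 700
  L-SEF: 564
  R-SEF: 564
  L-Par: 1043
  R-Par: 1043
runs_per_subject_schedule: null
bad_behavior:
  drop_rate: 0.0
  blink_rate: 0.0
  wrong_hemifield_rate: 0.0
feature_curves: false
run_univariate: true
run_eye_qc: true
n_background_voxels: 0
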