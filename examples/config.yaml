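# Full-experiment configuration for `vrmotorlab run-all --config ...`.
# Omitted keys fall back to the study defaults (see pipeline.RunConfig).

seed: 1
n_participants: 20
n_days: 7
blocks_per_day: 10

# success-rate bands of the difficulty regulator
band_lower: 0.50
band_upper: 0.75

# kinematic scoring
cutoff_hz: 10.0
filter_order: 4
error_floor_cm: 0.1
sparc_amp_threshold: 0.05
sparc_max_cutoff_hz: 20.0

alpha: 0.05

# practice -> assessment improvement mapping (0 disables any true effect)
practice_gain: 0.6
retention: 0.9

# synthetic learner population (calibration constants)
population:
  baseline_mean: 5.0
  baseline_sd: 1.2
  asymptote_gain_mean: 110.0
  asymptote_gain_sd: 15.0
  learning_rate_mean: 0.005
  learning_rate_sd: 0.0012
  learning_rate_bounds: [0.002, 0.012]
  slope: 2.5
  fp_propensity_range: [0.03, 0.12]
  periphery_penalty_range: [0.4, 1.0]
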