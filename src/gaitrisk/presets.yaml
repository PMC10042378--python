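# Shipped walker presets.
#
# All presets share the default nominal gait (step duration 1.0 s, step
# length 1.0 m) and differ along four axes:
#   * contraction - the strength of the step-to-step correction, which sets
#     the state noise amplitude the gait metrics can observe;
#   * failure_boundary - the size of the basin of attraction, which the
#     per-step metrics cannot observe (two walkers can move identically yet
#     tolerate different excursions before falling);
#   * fixed_point - a small offset of the periodic gait, shifting the mean
#     metrics between walkers;
#   * seed - the walker's waveform identity (per-channel template and gain
#     multipliers), the way distinct gaits have distinct waveforms.
# Together these span mean first passage times from ~10 steps (fragile) to
# beyond 10^8 (and ~10^12 under the SS0.5 timing, whose input gain is
# weakest), with the boundary axis leaving an irreducible residual in any
# metric-based fall-risk model.  The state grid always covers the failure
# band with 41 states.

train_01: {role: train, contraction: 0.3, fixed_point: 0.004,
           failure_boundary: 0.076, grid_halfwidth: 0.076, grid_spacing: 0.0038,
           seed: 101}
train_02: {role: train, contraction: 0.35, fixed_point: -0.006,
           failure_boundary: 0.0685, grid_halfwidth: 0.0685, grid_spacing: 0.003425,
           seed: 102}
train_03: {role: train, contraction: 0.4, fixed_point: 0.008,
           failure_boundary: 0.0715, grid_halfwidth: 0.0715, grid_spacing: 0.003575,
           seed: 103}
train_04: {role: train, contraction: 0.45, fixed_point: -0.01,
           failure_boundary: 0.068, grid_halfwidth: 0.068, grid_spacing: 0.0034,
           seed: 104}
train_05: {role: train, contraction: 0.5, fixed_point: 0.012,
           failure_boundary: 0.07, grid_halfwidth: 0.07, grid_spacing: 0.0035,
           seed: 105}
train_06: {role: train, contraction: 0.55, fixed_point: -0.004,
           failure_boundary: 0.0725, grid_halfwidth: 0.0725, grid_spacing: 0.003625,
           seed: 106}
train_07: {role: train, contraction: 0.6, fixed_point: 0.006,
           failure_boundary: 0.0685, grid_halfwidth: 0.0685, grid_spacing: 0.003425,
           seed: 107}
train_08: {role: train, contraction: 0.65, fixed_point: -0.008,
           failure_boundary: 0.0715, grid_halfwidth: 0.0715, grid_spacing: 0.003575,
           seed: 108}
train_09: {role: train, contraction: 0.7, fixed_point: 0.01,
           failure_boundary: 0.07, grid_halfwidth: 0.07, grid_spacing: 0.0035,
           seed: 109}
train_10: {role: train, contraction: 0.74, fixed_point: -0.012,
           failure_boundary: 0.068, grid_halfwidth: 0.068, grid_spacing: 0.0034,
           seed: 110}
train_11: {role: train, contraction: 0.78, fixed_point: 0.004,
           failure_boundary: 0.0725, grid_halfwidth: 0.0725, grid_spacing: 0.003625,
           seed: 111}
train_12: {role: train, contraction: 0.81, fixed_point: -0.006,
           failure_boundary: 0.0695, grid_halfwidth: 0.0695, grid_spacing: 0.003475,
           seed: 112}
train_13: {role: train, contraction: 0.84, fixed_point: 0.008,
           failure_boundary: 0.0705, grid_halfwidth: 0.0705, grid_spacing: 0.003525,
           seed: 113}
train_14: {role: train, contraction: 0.87, fixed_point: -0.01,
           failure_boundary: 0.069, grid_halfwidth: 0.069, grid_spacing: 0.00345,
           seed: 114}
train_15: {role: train, contraction: 0.9, fixed_point: 0.012,
           failure_boundary: 0.0715, grid_halfwidth: 0.0715, grid_spacing: 0.003575,
           seed: 115}
train_16: {role: train, contraction: 0.92, fixed_point: -0.004,
           failure_boundary: 0.072, grid_halfwidth: 0.072, grid_spacing: 0.0036,
           seed: 116}
train_17: {role: train, contraction: 0.94, fixed_point: 0.006,
           failure_boundary: 0.068, grid_halfwidth: 0.068, grid_spacing: 0.0034,
           seed: 117}
train_18: {role: train, contraction: 0.95, fixed_point: -0.008,
           failure_boundary: 0.071, grid_halfwidth: 0.071, grid_spacing: 0.00355,
           seed: 118}
train_19: {role: train, contraction: 0.96, fixed_point: 0.01,
           failure_boundary: 0.0695, grid_halfwidth: 0.0695, grid_spacing: 0.003475,
           seed: 119}
train_20: {role: train, contraction: 0.97, fixed_point: -0.012,
           failure_boundary: 0.0725, grid_halfwidth: 0.0725, grid_spacing: 0.003625,
           seed: 120}
val_01: {role: val, contraction: 0.33, fixed_point: 0.007,
         failure_boundary: 0.0705, grid_halfwidth: 0.0705, grid_spacing: 0.003525,
         seed: 201}
val_02: {role: val, contraction: 0.47, fixed_point: -0.009,
         failure_boundary: 0.0685, grid_halfwidth: 0.0685, grid_spacing: 0.003425,
         seed: 202}
val_03: {role: val, contraction: 0.6, fixed_point: 0.005,
         failure_boundary: 0.0715, grid_halfwidth: 0.0715, grid_spacing: 0.003575,
         seed: 203}
val_04: {role: val, contraction: 0.72, fixed_point: -0.011,
         failure_boundary: 0.0695, grid_halfwidth: 0.0695, grid_spacing: 0.003475,
         seed: 204}
val_05: {role: val, contraction: 0.83, fixed_point: 0.009,
         failure_boundary: 0.071, grid_halfwidth: 0.071, grid_spacing: 0.00355,
         seed: 205}
val_06: {role: val, contraction: 0.91, fixed_point: -0.005,
         failure_boundary: 0.069, grid_halfwidth: 0.069, grid_spacing: 0.00345,
         seed: 206}
# A deliberately unstable walker that falls within tens of steps; used for
# Monte-Carlo cross-checks of the first-passage machinery.
fragile: {role: extra, contraction: 0.90, fixed_point: 0.0,
          failure_boundary: 0.040, grid_halfwidth: 0.040, grid_spacing: 0.0040,
          seed: 301}
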