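# Example run configuration for the sprayroom CLI.
# All fields are optional; shown with their defaults unless noted.

scenario: trigger_50          # trigger_20 | trigger_50 | trigger_80 | propellant
scenario_overrides:           # any ScenarioSpec field
  sampling_interval_s: 1.0
# input_paths: []             # analyze measured CSVs instead of synthetics

outdir: runs/out
seed: 0

# preprocessing
background_window_min: 5.0    # pre-application background window
smooth_window_h: 0.0416667    # 2.5-min running average
reference_mass_g: 1.0         # normalization target (per gram applied)
# calibration: {slope: 1.0, intercept: 0.0}

# fitting
trim_fraction: 0.25
# fit_initial: 1.0            # defaults to lambda
fit_upper_bound: 1000.0

# metrics
durations_h: [0.1, 0.3]
cv_ddof: 1                    # 1 = sample sd, 0 = population sd

# sweep
sweep_ratios: [0.5, 1, 2, 5, 10]

log_level: INFO
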