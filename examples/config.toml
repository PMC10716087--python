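# Desk-scale example pipeline configuration.
#
# Generates a 12-participant synthetic cohort at 100 Hz (so the example runs
# in well under a minute), preprocesses it, and runs the cross-validated
# window analysis plus the behavioral models.  The study-scale conditions
# use sampling_rate_hz = 1000 with downsample_factor = 10.

[design]
variant = "exp1"
n_participants = 12
seed = 1
trace_duration_ms = 3100.0

[observer]
threshold_opacity_pct = 20.0
psychometric_slope = 0.15
lapse_rate = 0.02
validity_sensitivity_gain = 1.4
rt_location_ms = 600.0
rt_scale = 0.25

[pupil]
baseline_mm_mean = 5.0
baseline_mm_sd_between = 0.5
light_response_amplitude_mm = -1.0
breadth_slope_mm = 0.008
breadth_onset_ms = 1750.0
breadth_plateau_ms = 2500.0
slope_sd_between = 0.015
sampling_rate_hz = 100.0
au_gain = 500.0
au_offset = 1000.0

[preprocess]
downsample_factor = 1
mm_coeff_a = 0.002
mm_coeff_b = -2.0

[analysis]
search_start_ms = 750.0
search_end_ms = 3000.0
n_folds = 4
bin_ms = 10.0
window_ms = 100.0

[output]
out_dir = "pupilbreadth-out"
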