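# Demo cohort: one control group, one convulsant-like group (gamma-band
# bursts plus elevated fast oscillations), one suppressor-like group
# (reduced >15 Hz amplitude), 4 animals each, 150-s epochs at 2 kHz.

[run]
outdir = "lfpseize_demo_out"
seed = 7
log_level = "WARNING"

[input]
source = "synthetic"

[cohort]
n_per_group = 4
rate_hz = 2000.0
baseline = [0.0, 150.0]
exposure = [160.0, 310.0]

[[cohort.groups]]
label = "control"

[[cohort.groups]]
label = "convulsant 60uM"
n_bursts_exposure = 12
burst_band = "gamma"
burst_amplitude = 6.0

[cohort.groups.band_gain]
gamma = 1.8
high_gamma = 1.5
hfo = 1.5

[[cohort.groups]]
label = "suppressor 125uM"

[cohort.groups.band_gain]
beta = 0.5
gamma = 0.5
high_gamma = 0.5
hfo = 0.5

[preproc]
highpass_hz = 1.0
lowpass_hz = 500.0
filter_order = 4
zero_phase = true

[morse]
symmetry_gamma = 3.0
time_bandwidth = 60.0
voices_per_octave = 10
fmin_hz = 1.0
fmax_hz = 500.0

[detection]
threshold_sd = 2.0
event_duration = 1.0
min_separation = 1.0

[auc]
bin_seconds = 30.0

[stats]
control_label = "control"
family = "global"
alpha = 0.05
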