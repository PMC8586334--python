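# Simulation scenario mimicking the headline single-molecule condition
# (mean unwinding rate 44 bp/s, mean processivity 2300 bp on a 6.6 kbp
# nicked-flap tether sampled at 30 Hz).  These are SIMULATION DEFAULTS
# chosen to mirror published summary statistics, not ground truth of any
# real recording; pause/re-initiation rates are placeholders.

seed = 1
out_dir = "out"

[simulate]
n_traces = 25
frame_rate_hz = 30.0
duration_s = 180.0
force_pN = 30.0
velocity_bp_per_s = 44.0
mean_processivity_bp = 2300.0
pause_entry_per_s = 0.02
pause_exit_per_s = 0.5
reinitiation_per_s = 0.05
noise_sd_nm = 5.0

[polymer]
ds_persistence_nm = 45.0
ds_rise_nm_per_bp = 0.338
ss_kuhn_nm = 1.5
ss_contour_nm_per_nt = 0.56
temperature_K = 298.0

[geometry]
ds_bp_total = 6600
flap_nt = 40

[analysis]
penalty_scale = 10.0
velocity_pause_threshold_bp_per_s = 5.0
min_processivity_bp = 100.0
smoothing_window = 15

[mass]
tolerance_kDa = 20.0

[mass.components]
RPA = 114.0
Dna2 = 172.0
DNA = 25.0
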