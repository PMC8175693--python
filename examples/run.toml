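# Desk-scale run of the pin-matrix experiment (finishes in a few minutes).
# Drop n_samples / add matrices for the full ensemble.

[pattern]
h0_mm = 0.1   # raised-print height
Lw_mm = 4.0   # spine width
L1_mm = 1.0   # rib thickness

[scan]
speed_mm_per_s = 50.0
T_ms = 800.0
dt_ms = 0.01

[sweep]
matrices = ["PM1"]
rib_intervals_mm = [0.2, 0.4, 1.0, 1.4, 1.8, 2.0, 2.2, 3.0, 4.0]
n_samples = 5
seed = 1

[analysis]
bin_ms = 4.0
v_star_mV = 40.0
coupling_rule = "nearest"

[psych]
template = "unimodal_with_dips"
n_participants = 12
trials_per_pair = 4
seed = 1
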