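# Calibrated simulator defaults (re-derived; see docs/methods.md).
# At circumferences 54 / 72 / 90 cells these produce primary rings of
# 3 / 4 / 5 tentacles with ~18-cell spacing, periodic rings down the
# body and half-period alternation between successive rings.
# Values mirror the SimParams dataclass defaults; a consistency test
# keeps the two in sync.
D_a: 3.0
D_b: 3.0
D_c: 3.0
k_a: 0.0075
k_b: 0.12
k_c: 12.0
s_a: 1.0
s_b: 1.0
s_c: 1.0
T_a: 0.2
T_i: 1.1
T_ti: 4.71e-16
W: 72
L: 80
mouth_rows: 2
dt_fraction: 0.8
max_steps: 22000
max_tentacles: 26
init_warmup: 2400
init_interval: 700
noise_amp: 0.0002
seed: 0
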