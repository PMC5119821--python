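# Outcome-probability grid on a 4x4 cm slab (the full published layout;
# ~100 realizations x 1500 ms each is an overnight-to-days job on one core).
phi_values: [0.66, 0.68, 0.70, 0.72, 0.74]
tau_d_core_values: [0.25, 0.30, 0.35]
n_layers_values: [1, 3, 5, 10, 20]
R0_values: [1.4]
nx: 400
ny: 400
border_width: 0.2
n_realizations: 100
base_seed: 1
t_end: 1500.0
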