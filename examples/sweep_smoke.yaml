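# Minutes-scale smoke test of the sweep machinery on a small slab.
phi_values: [0.0, 0.70]
tau_d_core_values: [0.30]
n_layers_values: [3]
R0_values: [0.35]
nx: 100
ny: 100
border_width: 0.1
n_realizations: 2
base_seed: 3
t_end: 400.0
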