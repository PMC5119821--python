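# Reentry probability vs fibrotic-region radius at N = 10, tau_d = 0.30 ms.
phi_values: [0.71, 0.72, 0.73]
tau_d_core_values: [0.30]
n_layers_values: [10]
R0_values: [0.4, 0.6, 0.8, 1.0, 1.2, 1.4]
nx: 400
ny: 400
border_width: 0.2
n_realizations: 100
base_seed: 2
t_end: 1500.0
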