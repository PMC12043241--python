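n: 500
k: 20
a_mean: 1.8
a_sd: 0.5
scale: 1.7
threshold_scheme: sorted
difficulty_sd: 0.5
threshold_offsets:
- -1.5
- -0.5
- 0.5
- 1.5
rates:
- 0.1
- 0.3
methods:
- CIM
- EM
- MI
m: 5
mi_iterations: 100
mi_burn_in: 50
em_max_iter: 300
em_tol: 1.0e-05
gate_alpha: 0.05
run_gate: true
mi_pooled_indices: false
force_one_component: false
seed: 0
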