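n: 5000
k: 50
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
- 0.01
- 0.02
- 0.03
- 0.04
- 0.05
- 0.06
- 0.07
- 0.08
- 0.09
- 0.1
- 0.11
- 0.12
- 0.13
- 0.14
- 0.15
- 0.2
- 0.25
- 0.3
- 0.35
- 0.4
- 0.45
- 0.5
methods:
- CIM
- EM
- MI
m: 100
mi_iterations: 1000
mi_burn_in: 200
em_max_iter: 1000
em_tol: 1.0e-06
gate_alpha: 0.05
run_gate: true
mi_pooled_indices: false
force_one_component: false
seed: 0
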