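# 1-D bistable gradient system with white noise
name: example1
system:
  kind: bistable_1d
  params: {b: 5.0, c: 0.0}
  noise_eps: 0.3
  u0: [1.5]
simulation:
  dt: 0.01
  n_train: 10000
  n_predict: 10000
reservoir:
  n_nodes: 800
  input_scaling: 4.0
  degree: 4.0
  spectral_radius: 1.2e-3
  leak_rate: 0.2
  ridge_beta: 1.0e-8
noise:
  mode: empirical
  amplification: 1.1
evaluation:
  persistence: 50
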