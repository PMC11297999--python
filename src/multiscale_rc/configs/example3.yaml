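# 2-D bistable non-gradient system with white noise
name: example3
system:
  kind: nongradient_2d
  params: {a: 5.0, b: 5.0, c: 0.0}
  noise_eps: [0.3, 0.3]
  u0: [0.0, 2.0]
simulation:
  dt: 0.002
  n_train: 20000
  n_predict: 20000
reservoir:
  n_nodes: 1200
  input_scaling: 1.0
  degree: 2.2
  spectral_radius: 1.7e-3
  leak_rate: 0.3
  ridge_beta: 1.0e-7
noise:
  mode: empirical
  amplification: auto
evaluation:
  persistence: 50
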