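# slow-scale (deterministic) model for the Lorenz-driven double well
name: example2_set1
system:
  kind: lorenz_driven
  params: {b: 1.0, c: 0.0, psi: 0.08, eps: 0.5}
  u0: [-1.5, 1.0, 1.0, 1.0]
simulation:
  dt: 0.01
  n_train: 8000
  n_predict: 8000
reservoir:
  n_nodes: 1000
  input_scaling: 1.5
  degree: 3.2
  spectral_radius: 1.3e-3
  leak_rate: 0.25
  ridge_beta: 1.0e-7
evaluation:
  persistence: 50
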