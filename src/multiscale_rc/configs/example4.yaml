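# user-supplied experimental trajectory (e.g. protein end-to-end length);
# the sampling step of the recording is used as the time unit when unknown.
# training-length sweep for data-requirement checks: 25000 / 7500 / 6000 steps
name: example4
system:
  kind: external
  path: null            # set to a CSV file with the measured series
simulation:
  dt: 1.0
  n_train: 25000
  n_train_sweep: [25000, 7500, 6000]
  n_predict: 100000
reservoir:
  n_nodes: 800
  input_scaling: 0.04
  degree: 1.8
  spectral_radius: 0.021
  leak_rate: 0.22
  ridge_beta: 1.0e-6
noise:
  mode: empirical
  amplification: 1.0
evaluation:
  persistence: 50
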