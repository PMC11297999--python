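# second (noise) reservoir for the Lorenz-driven double well;
# trained on the 580 residual steps before the prediction start
# (550-650 steps are empirically suitable), predicting 300 steps
name: example2_set2
simulation:
  dt: 0.01
  n_train: 580
  n_predict: 300
reservoir:
  n_nodes: 800
  input_scaling: 0.996
  degree: 0.996
  spectral_radius: 0.806
  leak_rate: 0.065
  ridge_beta: 1.0e-7
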