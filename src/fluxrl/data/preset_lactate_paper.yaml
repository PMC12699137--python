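# Reference training setup of the lactate/ATPase case study:
# golden-batch ATPase tracking objective, 11 equidistant stepwise
# inputs over 9.5 h, 500 epochs x 500 episodes, learning rate 0.001.
environment: lactate
grid:
  t_end: 9.5
  n_intervals: 11
level: 0.0
objective:
  kind: reference_tracking
  switch_step: null   # null = choose the bang-bang switch by open-loop optimization
training:
  learning_rate: 0.001
  epochs: 500
  episodes_per_epoch: 500
  patience: 50
evaluation:
  n_episodes: 500
policy:
  constant_input: 873.0
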