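# Reference training setup of the fatty-acid/ACC case study:
# terminal-titer objective, 25 stepwise-constant 1-h inputs,
# 350 epochs x 500 episodes, learning rate 0.0075, patience 50.
environment: fatty_acid
grid:
  t_end: 25.0
  n_intervals: 25
level: 0.0
objective:
  kind: terminal_titer
training:
  learning_rate: 0.0075
  epochs: 350
  episodes_per_epoch: 500
  patience: 50
evaluation:
  n_episodes: 500
policy:
  constant_input: 40.0
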