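# End-to-end run on a generated fixture (reduced-width configuration).
seed: 1
outdir: scratch/run_demo
score_type: loewe
task: regression
split_strategy: pair_disjoint_kfold
k: 5
variant: full
fixture:
  seed: 1
  n_bits: 32
  embed_dim: 32
model:
  h: 4
  d: 32
  n_layers: 1
  cell_dim: 16
  head_widths: [128, 32]
  dropout: 0.1
  batch_size: 512
  lr: 0.0015
  patience: 20
  max_epochs: 80
  augment_swap: true
autoencoder:
  hidden: [64, 16]
  epochs: 200
  lr: 0.01
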