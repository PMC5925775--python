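seed: 11
data:
  train: data/train.conll
  dev: data/dev.conll
embeddings:
  word_dim: 50
  min_count: 5   # rare words (in particular novel entity names) map to UNK
model:
  gram_kernels: [1, 2, 3, 4, 5]
  gram_filters: 10
training:
  max_epochs: 100
  patience: 10
output:
  dir: run
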