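# 500-sentence cue corpus with an out-of-vocabulary train/dev/test split:
# test entity surfaces never occur in training.
n_sentences: 500
rng_seed: 11
noise_rate: 0.0
cue_window: 2
oov_split: true
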