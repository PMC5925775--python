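# ngramner

Named-entity recognition for biomedical text built on **local context**:
multi-width n-gram convolutions over character, word and part-of-speech
embeddings, topped by a linear-chain conditional random field (CRF).

Biomedical NER is hard for reasons general-domain NER is not: entity
vocabularies (genes, proteins, diseases, cell types) are enormous and grow
constantly, the same entity is written many ways, names are long, and so are
the sentences around them.  Models that read whole sentences (e.g.
bidirectional LSTMs) take in much that is irrelevant to any one mention.  The
architecture implemented here bets on the opposite: for most mentions a few
words of surrounding context — *"… levels of each of 20 subjects"* around a
protein name — carry the evidence needed to tag it, and a stack of
convolutions of several widths is exactly a bank of n-gram detectors over
that local context.

## The model

For a sentence `x₁ … xₙ`, each token is mapped to a vector

```
xᵢ = [ POS-tag embedding (15d) | word embedding (frozen, UNK for OOV) | char-CNN embedding ]
```

The character embedding convolves learned 25-d character vectors with kernel
sizes {2, 3, 4} (40 filters each), applies `tanh`, and max-pools each filter
over positions — robust to out-of-vocabulary and misspelled words.  Dropout
is applied to the concatenated vector during training.

The encoder slides filter banks of widths `J` (default 1…10, 50 filters per
width) over the token vectors.  For kernel size `j` the feature-map matrix
has `n − j + 1` rows; row `m` covers tokens `m … m+j−1`.  Word `i`'s
representation uses only its **correlated** feature maps — those whose
window contains `i`, the 1-based range `[max(1, i−j+1), min(i, n−j+1)]`:

```
Oᵢ = max over correlated rows of tanh(f_j),   concatenated over filters and j
```

A two-layer fully connected head turns this into a unary score matrix
`P ∈ ℝⁿˣᵗ` over the `t` IOB2 labels.  A linear-chain CRF with transition
matrix `T` (including start/end states) scores a label sequence `y` as

```
s(x, y) = Σᵢ₌₀ⁿ T[yᵢ, yᵢ₊₁] + Σᵢ₌₁ⁿ P[i, yᵢ]
```

Training maximizes the log-likelihood `s(x, y) − log Σ_ŷ exp s(x, ŷ)`
(forward recursion in log space); prediction is Viterbi decoding.  Evaluation
is chunk-level precision / recall / F1 with exact-span, exact-type matching.

The network — character CNN, n-gram encoder, CRF — is implemented in numpy
with hand-written, finite-difference-verified backward passes; optimization
is SGD with momentum 0.9, learning rate 0.002 with a 0.95 staircase decay
every 50 000 steps.

## Worked example

Train on a synthetic cue corpus (no downloads needed; the generator writes
CoNLL-style files in which each entity's type is signalled by a cue word
within 2 tokens of the mention):

```bash
ngramner generate --spec examples/corpus.yml --out data/
ngramner train    --config examples/train.yml
ngramner predict  --model run/checkpoint.npz --input data/test.conll --output pred.conll
ngramner evaluate --gold data/test.conll --pred pred.conll
```

With `examples/corpus.yml` generating a 500-sentence out-of-vocabulary split
(test entity surfaces never seen in training) and `examples/train.yml` using
kernels 1–5 with 10 filters, training prints

```
best epoch 40: dev F1 0.9932 (50 epochs run); checkpoint at run/checkpoint.npz
```

and evaluation of the held-out test split prints

```
type            tp    fp    fn    prec     rec      f1
overall        137     2     2  0.9856  0.9856  0.9856
Disease         77     2     0  0.9747  1.0000  0.9872
Gene            60     0     2  1.0000  0.9677  0.9836
```

i.e. the model recovers unseen entity names from character shape and assigns
their types from the in-window cues (chunk F1 0.99 here).  Restricting
kernels to `{1}` — no context visible — drops held-out F1 to ≈ 0.45 on the
same data, which is the local-context mechanism in one ablation.

The library is importable directly (`ngramner.fit`, `ngramner.viterbi_decode`,
`ngramner.evaluate_corpus`, …); the CLI is a thin layer over it.

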