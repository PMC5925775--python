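# Methods

## Model

`ngramner` tags token sequences with IOB2 labels for typed entity mentions.
The model is a composition of three parts.

**Input features.**  Each token is represented by the concatenation of three
embeddings, in this order: a 15-dimensional trainable POS-tag embedding, a
frozen word embedding with a shared `UNK` row for out-of-vocabulary words,
and a character-level CNN embedding.  The character CNN embeds each
character as a learned 25-dimensional vector, slides filter banks of widths
{2, 3, 4} (40 filters each) over the character matrix (valid convolution,
output length l − k + 1 for a word of l characters), applies `tanh`, and
max-pools each filter over positions, yielding 120 dimensions.  Words are
truncated at 40 characters and padded with a zero-pinned padding symbol up
to the largest kernel width, so every kernel has at least one valid window;
because the padding row is frozen at zero and biases start at zero, padding
cannot dominate the max-pool at initialization, and the padding row never
receives gradient.  Inverted dropout (default rate 0.5) is applied to the
concatenated vector in training mode only.

**n-gram encoder.**  Filter banks of widths `J` (default 1…10; 50 filters
per width; width set 1…12 suits corpora with longer mentions) are slid over
the sentence's token vectors.  A word's representation pools only its
*correlated* feature maps — those whose receptive window contains the word:
for word i (1-based) and kernel j, map indices `[max(1, i−j+1),
min(i, n−j+1)]`.  Per filter, the representation is the maximum of `tanh`
over that range (equivalently `tanh` of the maximum — `tanh` is monotone; we
compute `max(tanh(·))`).  Blocks are concatenated over filters, then over
kernel sizes in ascending order.  A two-layer head (affine → `tanh` →
affine, hidden width 100) produces one raw score per label; no softmax is
applied because the CRF consumes unnormalized scores.  Sentences shorter
than `max(J)` are right-padded with zero token vectors; padded positions
yield no output rows and (being all-zero, with no dropout applied to them)
contribute nothing that training could exploit.

**CRF.**  A linear-chain CRF over the t labels plus distinguished start and
end states.  The transition matrix is (t+2)×(t+2); transitions into start
and out of end are pinned at −∞ and carry no gradient.  The log-partition
uses the forward recursion in log space (a max-shifted log-sum-exp, stable
for scores up to ±1e3 and tolerant of −∞ entries); gradients of the negative
log-likelihood are the classical forward–backward expected counts minus
observed counts; decoding is Viterbi with ties broken toward the lowest
label index at each backtrack step.  Start/end transitions are included in
both training and decoding.  No IOB2-legality mask is imposed during
decoding — the transitions learn legality from data — and predicted label
streams are decoded to chunks under the conventional repair rule (an `I-t`
that does not continue a `t` chunk opens one); a `strict` mode that raises
instead is available for validating gold data.

## Differentiation and optimization

No deep-learning framework is used: forward and backward passes for the
character CNN, the n-gram encoder, the head and the CRF are written directly
in numpy.  Max-pool gradients are routed through recorded argmaxes; window
(im2col) gradients are scatter-added back to token vectors; embedding
gradients are scatter-added to table rows.  The backward pass is verified
against central finite differences for every parameter group in the test
suite (tolerance 1e-5 per coordinate on small models; the CRF alone at
1e-4 as an acceptance check).

Initialization: embedding tables are sampled uniformly from
±√(3/dim); convolution filters and fully connected layers use
Xavier-uniform bounds ±√(6/(fan_in+fan_out)); all biases start at exactly
zero.  Optimization is SGD with momentum 0.9, initial learning rate 0.002,
and a staircase decay `lr₀ · 0.95^⌊step/50000⌋` where a step is one
mini-batch update.  Batches (default 16 sentences) are implemented as
gradient accumulation over per-sentence passes followed by one update, so no
padded positions ever enter the loss.  Gradients are clipped at global norm
5.0 (an addition; standard for CRF-topped networks).  The word-embedding
table is frozen throughout — it is excluded from the gradient dictionary and
`fit` asserts bitwise equality before/after training.  Character and POS
embeddings train with the rest of the network.

Model selection: one epoch log record per epoch (mean NLL, dev chunk
P/R/F1, lr); the checkpoint with the best dev F1 is kept (F1, not loss, is
the selection criterion), with early stopping after 10 epochs without
improvement and a cap of 100 epochs.  All randomness — initialization,
shuffling, dropout — derives from one seed; identical seeds give bitwise
identical logs.

## Synthetic data: what it emulates, what it does not

The generator realizes the local-context premise: an entity's type is
signalled by a cue word within `cue_window` (default 2) tokens of the span.
Sentences are 15–30 tokens (biomedical sentences are long); each carries a
Poisson(1.5)-truncated number of entities; entity surfaces are 1–2 token
names shaped like biomedical identifiers (letter stem, hyphen, digits);
`noise_rate` is the probability a cue is dropped.  POS tags come from a
small closed set correlated with token role, standing in for a real tagger.

Two deliberate calibrations mirror properties of real corpora:

- **Open vocabulary.**  The default surface inventory (400 per type) is
  large relative to a 500-sentence corpus, so most names occur once or
  twice.  Entity vocabularies in the wild are effectively unbounded;
  memorizing surfaces does not solve the task, and with small inventories a
  high-capacity model does exactly that instead of learning context.
- **OOV word table.**  The natural frozen word table covers the background
  vocabulary (fillers and cues) but not entity names, which therefore map to
  `UNK` — the out-of-vocabulary situation character embeddings exist for.
  `background_vocabulary()` provides it; the CLI reaches the same state via
  a `min_count` frequency cutoff.

The OOV split (`generate_char_oov_split`) partitions each type's surfaces
disjointly across train/dev/test, so held-out evaluation cannot be solved by
recall of training surfaces.  Because all types share one surface
morphology, character shape supports entity *detection* but not *typing*;
the in-window cue is the only type signal.  Consequently a model whose
kernels cover the cue window learns the task (held-out chunk F1 ≥ 0.95 on
the 500-sentence corpus), while the same model restricted to width-1 kernels
— blind to context — collapses to near coin-flip typing (F1 ≈ 0.45–0.55).
An optional per-type token suffix can instead give each type a recognizable
morphology, for experiments where character features alone should suffice.

What the generator does *not* emulate: realistic language (fillers are drawn
i.i.d. from a small list), annotation noise and inconsistency, nested or
discontinuous mentions, long entities (> 2 tokens), ambiguous cues, or any
specific corpus's label distribution.  Passing the synthetic suites
demonstrates that the architecture, gradients and training loop work and
that the model exploits local context; it does not predict benchmark scores
on real corpora, which require the corresponding downloads and far longer
training.

## Problem sizes in the test suite

The tests exercise the stack at sizes chosen to probe correctness rather
than scale: exhaustive-enumeration CRF oracles at n ≤ 6, t ≤ 4 (where all
t^n sequences are enumerable); brute-force convolution and window
enumeration oracles at n ≤ 12; training checks on a 500-sentence corpus
with kernels 1–5 and 10 filters per width (the two training runs finish in
about two minutes on one CPU).  The CLI worked example in the README uses
the same 500-sentence configuration.

## Design choices where the design was open

- Dropout rate 0.5 (applied to the input concatenation only; nowhere else).
- Word lookup is case-sensitive, with an optional lowercase fallback.
- Unknown POS tags map to a dedicated learned row.
- Chunk coordinates are 0-based half-open token indices.
- Exact-span, exact-type matching; micro-averaged overall scores (overall
  counts equal per-type sums).
- `decode_chunks` repair policy defaults to the conventional rule above.
- Checkpoints are single-file `.npz` archives of named arrays plus a JSON
  metadata record with a version field.

## Known limitations

Overlapping and discontinuous mentions are unsupported (IOB2 cannot encode
them).  Tokenization and POS tagging of raw text are out of scope: input is
token-per-line, and the POS column is optional.  Training is O(sentences ×
tokens × Σⱼ j·D) per epoch in pure numpy — fine at desk scale, not tuned
for corpora of 10⁴⁺ sentences.  The evaluator implements strict matching
only, not task-specific alternate-boundary credit schemes.
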