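import numpy as np
import pytest

from ngramner import (
    ModelConfig,
    SyntheticSpec,
    WordEmbeddingTable,
    build_model,
    generate_corpus,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def tiny_model(sentences, seed=0, **config_overrides):
    """Small model over a corpus: cheap dims, deterministic init."""
    cfg = dict(
        char_dim=5,
        char_kernels=(2, 3),
        char_filters=4,
        pos_dim=3,
        gram_kernels=(1, 2, 3),
        gram_filters=5,
        head_hidden=8,
        dropout_rate=0.0,
    )
    cfg.update(config_overrides)
    vocab = sorted({t.surface for s in sentences for t in s.tokens})
    rng = np.random.default_rng(seed)
    table = WordEmbeddingTable.random(vocab, 10, rng)
    return build_model(sentences, table, ModelConfig(**cfg), rng=rng)


@pytest.fixture
def small_corpus():
    sentences, chunks = generate_corpus(
        SyntheticSpec(n_sentences=12, sentence_length=(5, 10), rng_seed=42)
    )
    return sentences, chunks
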