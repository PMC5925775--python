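"""Per-token input features: character-CNN embedding, word-embedding lookup,
POS-tag embedding, concatenation, and input dropout.

The character embedding makes the model robust to out-of-vocabulary and
misspelled words: each character is a learned d-dimensional vector (d = 25 by
default), a word is the l x d matrix of its characters, and for each kernel
size k a bank of filters is slid over the matrix (valid convolution, output
length l - k + 1), passed through tanh, and max-pooled to one value per
filter.  The defaults are kernel sizes {2, 3, 4} with 40 filters each, giving
a 120-dimensional character embedding.

Word embeddings are looked up in a fixed (frozen) table, with a shared UNK
row for unknown words.  POS tags get a small trainable table (15 dimensions).
"""

from __future__ import annotations

import string
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .corpus import ParseError, Token

PAD_CHAR = "<pad>"
UNK_CHAR = "<unk>"
UNK_WORD = "UNK"
UNK_POS = "<unk-pos>"

_DEFAULT_CHARS = string.ascii_letters + string.digits + string.punctuation


def uniform_embedding_bound(dim: int) -> float:
    """Half-width of the uniform embedding initializer, sqrt(3 / dim)."""
    return float(np.sqrt(3.0 / dim))


def init_embedding(shape: tuple[int, ...], rng: np.random.Generator) -> np.ndarray:
    """Embedding initializer: entries ~ Uniform(-sqrt(3/dim), +sqrt(3/dim)),
    where dim is the trailing (vector) dimension."""
    b = uniform_embedding_bound(shape[-1])
    return rng.uniform(-b, b, size=shape)


class CharAlphabet:
    """Ordered character set plus distinguished padding and unknown symbols.

    Index 0 is the padding symbol; its embedding row is frozen at zero so
    padding can never win the max-pool.
    """

    def __init__(self, characters: str = _DEFAULT_CHARS, dim: int = 25):
        if dim < 1:
            raise ValueError("character embedding dimension must be >= 1")
        seen: list[str] = []
        for ch in characters:
            if ch in (PAD_CHAR, UNK_CHAR):
                raise ValueError("padding/unknown symbols cannot appear in the alphabet")
            if ch not in seen:
                seen.append(ch)
        self.symbols: tuple[str, ...] = (PAD_CHAR, UNK_CHAR) + tuple(seen)
        self._index = {ch: i for i, ch in enumerate(self.symbols)}
        self.dim = dim

    pad_index = 0
    unk_index = 1

    def __len__(self) -> int:
        return len(self.symbols)

    def index(self, ch: str) -> int:
        return self._index.get(ch, self.unk_index)

    def indices(self, word: str, max_len: int, min_len: int = 1) -> np.ndarray:
        """Character indices for a word, truncated at ``max_len`` and padded
        with the padding symbol up to ``min_len``."""
        idx = [self.index(ch) for ch in word[:max_len]]
        if len(idx) < min_len:
            idx += [self.pad_index] * (min_len - len(idx))
        return np.asarray(idx, dtype=int)


@dataclass
class CharCNNParams:
    """Character-level CNN: embedding table + one filter bank per kernel size.

    ``embeddings`` has one row per alphabet symbol (row 0 = padding, frozen at
    zero).  ``weights[k]`` has shape (k * d, filters(k)) — the filter for a
    window of k characters, flattened — and ``biases[k]`` length filters(k).
    """

    alphabet: CharAlphabet
    embeddings: np.ndarray
    weights: dict[int, np.ndarray]
    biases: dict[int, np.ndarray]

    def __post_init__(self):
        self.embeddings[CharAlphabet.pad_index] = 0.0

    @property
    def kernel_sizes(self) -> tuple[int, ...]:
        return tuple(sorted(self.weights))

    @property
    def output_dim(self) -> int:
        return sum(w.shape[1] for w in self.weights.values())

    @classmethod
    def create(
        cls,
        alphabet: CharAlphabet,
        kernel_sizes: tuple[int, ...] = (2, 3, 4),
        filters: int = 40,
        rng: np.random.Generator | None = None,
    ) -> "CharCNNParams":
        from .training import init_layer  # deferred: avoid import cycle

        rng = rng if rng is not None else np.random.default_rng(0)
        emb = init_embedding((len(alphabet), alphabet.dim), rng)
        weights, biases = {}, {}
        for k in kernel_sizes:
            weights[k], biases[k] = init_layer((k * alphabet.dim, filters), rng)
        return cls(alphabet, emb, weights, biases)


def char_matrix(
    word: str,
    params: CharCNNParams,
    max_len: int = 40,
) -> np.ndarray:
    """The word's l x d character matrix, truncated at ``max_len`` characters
    and padded (zero rows) to at least the largest kernel size so every
    kernel has one valid window."""
    if not word:
        raise ValueError("word must be non-empty")
    idx = params.alphabet.indices(word, max_len, min_len=max(params.kernel_sizes))
    return params.embeddings[idx]


def _windows(M: np.ndarray, k: int) -> np.ndarray:
    """All length-k windows of rows of M, flattened: (l-k+1, k*d)."""
    l, d = M.shape
    if l < k:
        raise ValueError(f"matrix with {l} rows cannot host a size-{k} kernel")
    v = np.lib.stride_tricks.sliding_window_view(M, (k, d)).reshape(l - k + 1, k * d)
    return v


def char_embed(M: np.ndarray, params: CharCNNParams) -> np.ndarray:
    """Character embedding of a word matrix: per kernel size and filter,
    tanh of the valid convolution, max-pooled over positions; concatenated
    over filters and kernel sizes (ascending)."""
    parts = []
    for k in params.kernel_sizes:
        Z = _windows(M, k) @ params.weights[k] + params.biases[k]
        parts.append(np.tanh(Z).max(axis=0))
    return np.concatenate(parts)


class WordEmbeddingTable:
    """Frozen word-vector table with a designated UNK row for unknown words.

    Lookup is case-sensitive; with ``lowercase_fallback`` a missing word is
    retried lowercased before falling back to UNK.
    """

    def __init__(
        self,
        vocabulary: dict[str, int],
        matrix: np.ndarray,
        lowercase_fallback: bool = False,
    ):
        if UNK_WORD not in vocabulary:
            raise ValueError(f"table must contain the {UNK_WORD!r} row")
        self.vocabulary = vocabulary
        self.matrix = matrix
        self.lowercase_fallback = lowercase_fallback
        self.unk_index = vocabulary[UNK_WORD]

    @property
    def dim(self) -> int:
        return self.matrix.shape[1]

    def __len__(self) -> int:
        return len(self.vocabulary)

    def index(self, word: str) -> int:
        i = self.vocabulary.get(word)
        if i is None and self.lowercase_fallback:
            i = self.vocabulary.get(word.lower())
        return self.unk_index if i is None else i

    def vector(self, word: str) -> np.ndarray:
        return self.matrix[self.index(word)]

    @classmethod
    def random(
        cls,
        words: list[str],
        dim: int,
        rng: np.random.Generator,
        lowercase_fallback: bool = False,
    ) -> "WordEmbeddingTable":
        """Fixed random table over a vocabulary (plus UNK); used when no
        pre-trained embedding file is supplied."""
        vocab: dict[str, int] = {}
        for w in words:
            if w not in vocab:
                vocab[w] = len(vocab)
        if UNK_WORD not in vocab:
            vocab[UNK_WORD] = len(vocab)
        matrix = init_embedding((len(vocab), dim), rng)
        return cls(vocab, matrix, lowercase_fallback)


def load_word2vec_text(
    path: str | Path,
    rng: np.random.Generator | None = None,
    lowercase_fallback: bool = False,
) -> WordEmbeddingTable:
    """Read a word2vec text-format table: header line ``vocab_size dim``,
    then one ``word v1 ... v_dim`` row per line.  A UNK row is appended if
    the file has none (uniform +-sqrt(3/dim), seeded via ``rng``)."""
    rng = rng if rng is not None else np.random.default_rng(0)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ParseError("expected header 'vocab_size dim'", line=1)
        n, dim = int(header[0]), int(header[1])
        vocab: dict[str, int] = {}
        rows: list[np.ndarray] = []
        for lineno, line in enumerate(fh, start=2):
            cols = line.rstrip("\n").split()
            if not cols:
                continue
            if len(cols) != dim + 1:
                raise ParseError(
                    f"expected {dim} values for word {cols[0]!r}, got {len(cols) - 1}",
                    line=lineno,
                )
            if cols[0] in vocab:
                raise ParseError(f"duplicate word {cols[0]!r}", line=lineno)
            vocab[cols[0]] = len(rows)
            rows.append(np.asarray(cols[1:], dtype=float))
    if len(rows) != n:
        raise ParseError(f"header promised {n} rows, file has {len(rows)}")
    if UNK_WORD not in vocab:
        vocab[UNK_WORD] = len(rows)
        rows.append(init_embedding((dim,), rng))
    return WordEmbeddingTable(vocab, np.vstack(rows), lowercase_fallback)


def save_word2vec_text(table: WordEmbeddingTable, path: str | Path) -> None:
    words = sorted(table.vocabulary, key=table.vocabulary.get)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{len(words)} {table.dim}\n")
        for w in words:
            vec = " ".join(repr(float(v)) for v in table.matrix[table.vocabulary[w]])
            fh.write(f"{w} {vec}\n")


class PosEmbeddingTable:
    """Trainable POS-tag embedding (15 dimensions by default); unseen tags at
    prediction time map to a dedicated learned row."""

    def __init__(self, tags: list[str], dim: int = 15, rng: np.random.Generator | None = None):
        rng = rng if rng is not None else np.random.default_rng(0)
        uniq: list[str] = []
        for t in tags:
            if t not in uniq:
                uniq.append(t)
        self.tags: tuple[str, ...] = tuple(uniq) + (UNK_POS,)
        self._index = {t: i for i, t in enumerate(self.tags)}
        self.matrix = init_embedding((len(self.tags), dim), rng)

    @property
    def dim(self) -> int:
        return self.matrix.shape[1]

    def index(self, tag: str | None) -> int:
        if tag is None:
            return self._index[UNK_POS]
        return self._index.get(tag, self._index[UNK_POS])

    def vector(self, tag: str | None) -> np.ndarray:
        return self.matrix[self.index(tag)]


def dropout_mask(
    shape: tuple[int, ...], rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Inverted-dropout mask: zeros with probability ``rate``, survivors
    scaled by 1/(1-rate) so the expectation is unchanged."""
    if not 0.0 <= rate < 1.0:
        raise ValueError("dropout rate must be in [0, 1)")
    if rate == 0.0:
        return np.ones(shape)
    return rng.binomial(1, 1.0 - rate, size=shape) / (1.0 - rate)


def token_vector(
    token: Token,
    word_table: WordEmbeddingTable,
    pos_table: PosEmbeddingTable,
    char_params: CharCNNParams,
    dropout_rate: float = 0.0,
    training: bool = False,
    rng: np.random.Generator | None = None,
    max_word_len: int = 40,
) -> np.ndarray:
    """The model's input vector for one token:
    concat(POS embedding, word embedding, character-CNN embedding), with
    inverted dropout applied in training mode only."""
    char_vec = char_embed(char_matrix(token.surface, char_params, max_word_len), char_params)
    vec = np.concatenate(
        [pos_table.vector(token.pos), word_table.vector(token.surface), char_vec]
    )
    if training and dropout_rate > 0.0:
        if rng is None:
            raise ValueError("training-mode dropout needs an rng")
        vec = vec * dropout_mask(vec.shape, dropout_rate, rng)
    return vec
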