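"""The assembled tagger: embeddings -> n-gram CNN encoder -> CRF.

This module owns the trainable-parameter container, the differentiable
forward pass producing the unary score matrix P, the hand-written backward
pass (the gradients the optimizer consumes), Viterbi prediction, and
checkpoint serialization.

Gradient bookkeeping honours the parameter-group contract: character
embeddings, POS embeddings, all convolution filters, the scoring head and
the CRF transitions are trained; the word-embedding table is frozen (it
never appears in the gradient dictionary), and the character padding row is
pinned at zero.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from . import crf
from .corpus import LabelAlphabet, Sentence
from .embeddings import (
    CharAlphabet,
    CharCNNParams,
    PosEmbeddingTable,
    WordEmbeddingTable,
    dropout_mask,
)
from .encoder import NgramCNNParams, conv_maps, unary_scores, word_representation

CHECKPOINT_VERSION = 1


@dataclass
class ModelConfig:
    """Architecture hyperparameters (embedding widths, kernel sets, head)."""

    char_dim: int = 25
    char_kernels: tuple[int, ...] = (2, 3, 4)
    char_filters: int = 40
    pos_dim: int = 15
    max_word_len: int = 40
    gram_kernels: tuple[int, ...] = tuple(range(1, 11))
    gram_filters: int = 50
    head_hidden: int = 100
    dropout_rate: float = 0.5

    def __post_init__(self):
        self.char_kernels = tuple(self.char_kernels)
        self.gram_kernels = tuple(self.gram_kernels)


@dataclass
class Model:
    config: ModelConfig
    labels: LabelAlphabet
    word_table: WordEmbeddingTable
    pos_table: PosEmbeddingTable
    char_params: CharCNNParams
    gram_params: NgramCNNParams
    transitions: np.ndarray

    @property
    def input_dim(self) -> int:
        return self.pos_table.dim + self.word_table.dim + self.char_params.output_dim

    def trainable_arrays(self) -> dict[str, np.ndarray]:
        """Named views of every trainable array (word table excluded)."""
        out = {"char_E": self.char_params.embeddings, "pos_E": self.pos_table.matrix}
        for k in self.char_params.kernel_sizes:
            out[f"char_W{k}"] = self.char_params.weights[k]
            out[f"char_b{k}"] = self.char_params.biases[k]
        for j in self.gram_params.kernel_sizes:
            out[f"gram_W{j}"] = self.gram_params.weights[j]
            out[f"gram_b{j}"] = self.gram_params.biases[j]
        out["head_w1"] = self.gram_params.head_w1
        out["head_b1"] = self.gram_params.head_b1
        out["head_w2"] = self.gram_params.head_w2
        out["head_b2"] = self.gram_params.head_b2
        out["T"] = self.transitions
        return out


def build_model(
    train_sentences: list[Sentence],
    word_table: WordEmbeddingTable,
    config: ModelConfig | None = None,
    labels: LabelAlphabet | None = None,
    rng: np.random.Generator | int | None = None,
) -> Model:
    """Assemble a freshly initialized model.

    The label alphabet and the POS-tag inventory are built from the training
    corpus only; the word table is supplied (pre-trained or fixed random) and
    stays frozen.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    config = config if config is not None else ModelConfig()
    if labels is None:
        labels = LabelAlphabet.from_corpus(train_sentences)
    pos_tags = []
    for s in train_sentences:
        for t in s.tokens:
            if t.pos is not None and t.pos not in pos_tags:
                pos_tags.append(t.pos)
    char_alphabet = CharAlphabet(dim=config.char_dim)
    char_params = CharCNNParams.create(
        char_alphabet, config.char_kernels, config.char_filters, rng
    )
    pos_table = PosEmbeddingTable(pos_tags, dim=config.pos_dim, rng=rng)
    input_dim = pos_table.dim + word_table.dim + char_params.output_dim
    gram_params = NgramCNNParams.create(
        input_dim,
        len(labels),
        config.gram_kernels,
        config.gram_filters,
        config.head_hidden,
        rng,
    )
    transitions = crf.make_transitions(len(labels))
    return Model(config, labels, word_table, pos_table, char_params, gram_params, transitions)


# ---------------------------------------------------------------------------
# forward
# ---------------------------------------------------------------------------

def _slide(M: np.ndarray, k: int, axis: int) -> np.ndarray:
    return np.lib.stride_tricks.sliding_window_view(M, k, axis=axis)


def _encode_tokens(
    model: Model,
    sentence: Sentence,
    training: bool,
    rng: np.random.Generator | None,
) -> tuple[np.ndarray, dict]:
    """Token vectors X (n x D) plus the cache the backward pass needs."""
    cfg, cp = model.config, model.char_params
    n = len(sentence)
    d = cp.alphabet.dim
    maxk = max(cp.kernel_sizes)

    lengths = np.array(
        [max(min(len(t.surface), cfg.max_word_len), maxk) for t in sentence.tokens]
    )
    L = int(lengths.max())
    idx = np.full((n, L), CharAlphabet.pad_index, dtype=int)
    for i, tok in enumerate(sentence.tokens):
        ci = cp.alphabet.indices(tok.surface, cfg.max_word_len)
        idx[i, : len(ci)] = ci
    M = cp.embeddings[idx]  # (n, L, d)

    char_cache: dict[int, dict] = {}
    char_parts = []
    positions = np.arange(L - min(cp.kernel_sizes) + 1)
    for k in cp.kernel_sizes:
        P = L - k + 1
        A = _slide(M, k, axis=1).transpose(0, 1, 3, 2).reshape(n, P, k * d)
        H = np.tanh(A @ cp.weights[k] + cp.biases[k])  # (n, P, F)
        valid = positions[:P][None, :] < (lengths - k + 1)[:, None]
        Hm = np.where(valid[:, :, None], H, -np.inf)
        amax = Hm.argmax(axis=1)  # (n, F)
        pooled = np.take_along_axis(Hm, amax[:, None, :], axis=1)[:, 0, :]
        char_parts.append(pooled)
        char_cache[k] = {"A": A, "amax": amax, "pooled": pooled}
    char_vec = np.concatenate(char_parts, axis=1)

    pos_idx = np.array([model.pos_table.index(t.pos) for t in sentence.tokens])
    word_idx = np.array([model.word_table.index(t.surface) for t in sentence.tokens])
    X = np.concatenate(
        [model.pos_table.matrix[pos_idx], model.word_table.matrix[word_idx], char_vec],
        axis=1,
    )

    mask = None
    if training and cfg.dropout_rate > 0.0:
        if rng is None:
            raise ValueError("training-mode dropout needs an rng")
        mask = dropout_mask(X.shape, cfg.dropout_rate, rng)
        X = X * mask

    cache = {
        "idx": idx,
        "char": char_cache,
        "pos_idx": pos_idx,
        "mask": mask,
        "n": n,
    }
    return X, cache


def _encode_sentence(
    model: Model, X: np.ndarray
) -> tuple[np.ndarray, dict]:
    """Unary scores P (n x t) from token vectors, with backward cache."""
    gp = model.gram_params
    n, D = X.shape
    J = gp.kernel_sizes
    N = max(n, max(J))
    Xp = X if N == n else np.vstack([X, np.zeros((N - n, D))])

    maps: dict[int, np.ndarray] = {}
    pooled_all: dict[int, np.ndarray] = {}
    rowsel: dict[int, np.ndarray] = {}
    parts = []
    for j in J:
        F = _windows_matmul(Xp, gp.weights[j], gp.biases[j], j)  # (N-j+1, filters)
        maps[j] = F
        Th = np.tanh(F)
        pad = np.full((j - 1, Th.shape[1]), -np.inf)
        ThP = np.vstack([pad, Th, pad]) if j > 1 else Th
        # word i (0-based) pools ThP rows i..i+j-1 == original rows i-j+1..i clipped
        W = _slide(ThP, j, axis=0)[:n]  # (n, filters, j)
        arg = W.argmax(axis=2)  # (n, filters) position within window
        pooled = np.take_along_axis(W, arg[:, :, None], axis=2)[:, :, 0]
        rows = arg + np.arange(n)[:, None] - (j - 1)  # original map row per (word, filter)
        pooled_all[j] = pooled
        rowsel[j] = rows
        parts.append(pooled)
    R = np.concatenate(parts, axis=1)  # (n, filters * |J|)

    Z1 = R @ gp.head_w1 + gp.head_b1
    H1 = np.tanh(Z1)
    P = H1 @ gp.head_w2 + gp.head_b2

    cache = {"Xp": Xp, "maps": maps, "pooled": pooled_all, "rows": rowsel,
             "R": R, "H1": H1, "N": N, "n": n}
    return P, cache


def _windows_matmul(X: np.ndarray, W: np.ndarray, b: np.ndarray, j: int) -> np.ndarray:
    n, D = X.shape
    A = _slide(X, j, axis=0).transpose(0, 2, 1).reshape(n - j + 1, j * D)
    return A @ W + b


def sentence_scores(
    model: Model,
    sentence: Sentence,
    training: bool = False,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Unary label-score matrix P (true token count x labels)."""
    X, _ = _encode_tokens(model, sentence, training, rng)
    P, _ = _encode_sentence(model, X)
    return P


def predict_labels(model: Model, sentence: Sentence) -> list[str]:
    """Viterbi-decoded IOB2 labels for one sentence."""
    P = sentence_scores(model, sentence, training=False)
    path, _ = crf.viterbi_decode(P, model.transitions)
    return model.labels.decode(path)


def predict_corpus(model: Model, sentences: list[Sentence]) -> list[list[str]]:
    return [predict_labels(model, s) for s in sentences]


# ---------------------------------------------------------------------------
# backward
# ---------------------------------------------------------------------------

def loss_and_gradients(
    model: Model,
    sentence: Sentence,
    rng: np.random.Generator | None = None,
    training: bool = True,
) -> tuple[float, dict[str, np.ndarray]]:
    """CRF negative log-likelihood of the sentence's gold labels and its
    gradient for every trainable array (same keys as ``trainable_arrays``)."""
    y = np.asarray(model.labels.encode(sentence.gold_labels))
    X, tok_cache = _encode_tokens(model, sentence, training, rng)
    P, enc_cache = _encode_sentence(model, X)
    nll, dP, dT = crf.nll_and_gradients(P, model.transitions, y)

    gp = model.gram_params
    grads: dict[str, np.ndarray] = {"T": dT}

    # scoring head
    H1, R = enc_cache["H1"], enc_cache["R"]
    grads["head_w2"] = H1.T @ dP
    grads["head_b2"] = dP.sum(axis=0)
    dH1 = dP @ gp.head_w2.T
    dZ1 = dH1 * (1.0 - H1 * H1)
    grads["head_w1"] = R.T @ dZ1
    grads["head_b1"] = dZ1.sum(axis=0)
    dR = dZ1 @ gp.head_w1.T

    # n-gram convolutions, routed through the max-pool argmaxes
    n, N = enc_cache["n"], enc_cache["N"]
    Xp = enc_cache["Xp"]
    D = Xp.shape[1]
    dX = np.zeros_like(Xp)
    col = 0
    ff = np.arange(gp.filters)[None, :]
    for j in gp.kernel_sizes:
        g = dR[:, col : col + gp.filters]
        col += gp.filters
        pooled, rows = enc_cache["pooled"][j], enc_cache["rows"][j]
        dF = np.zeros_like(enc_cache["maps"][j])
        np.add.at(dF, (rows, np.broadcast_to(ff, rows.shape)), g * (1.0 - pooled * pooled))
        A = _slide(Xp, j, axis=0).transpose(0, 2, 1).reshape(N - j + 1, j * D)
        grads[f"gram_W{j}"] = A.T @ dF
        grads[f"gram_b{j}"] = dF.sum(axis=0)
        dA = (dF @ gp.weights[j].T).reshape(N - j + 1, j, D)
        for o in range(j):
            dX[o : o + N - j + 1] += dA[:, o, :]
    dX = dX[:n]
    if tok_cache["mask"] is not None:
        dX = dX * tok_cache["mask"]

    # split token-vector gradient: POS | word (frozen, dropped) | char
    p_e, w_e = model.pos_table.dim, model.word_table.dim
    grads["pos_E"] = np.zeros_like(model.pos_table.matrix)
    np.add.at(grads["pos_E"], tok_cache["pos_idx"], dX[:, :p_e])
    dchar = dX[:, p_e + w_e :]

    cp = model.char_params
    idx = tok_cache["idx"]
    L = idx.shape[1]
    d = cp.alphabet.dim
    dM = np.zeros((n, L, d))
    col = 0
    for k in cp.kernel_sizes:
        F = cp.weights[k].shape[1]
        gk = dchar[:, col : col + F]
        col += F
        cc = tok_cache["char"][k]
        Pk = L - k + 1
        dZ = np.zeros((n, Pk, F))
        ii = np.arange(n)[:, None]
        dZ[ii, cc["amax"], np.arange(F)[None, :]] = gk * (1.0 - cc["pooled"] ** 2)
        A = cc["A"]  # (n, Pk, k*d)
        grads[f"char_W{k}"] = A.reshape(n * Pk, k * d).T @ dZ.reshape(n * Pk, F)
        grads[f"char_b{k}"] = dZ.sum(axis=(0, 1))
        dA = (dZ @ cp.weights[k].T).reshape(n, Pk, k, d)
        for o in range(k):
            dM[:, o : o + Pk, :] += dA[:, :, o, :]
    dE = np.zeros_like(cp.embeddings)
    np.add.at(dE, idx, dM)
    dE[CharAlphabet.pad_index] = 0.0  # padding row stays pinned at zero
    grads["char_E"] = dE

    return nll, grads


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: Model, path) -> None:
    """Single-file archive of all named arrays plus a JSON metadata record."""
    meta = {
        "version": CHECKPOINT_VERSION,
        "config": asdict(model.config),
        "entity_types": list(model.labels.entity_types),
        "char_symbols": list(model.char_params.alphabet.symbols[2:]),
        "pos_tags": list(model.pos_table.tags[:-1]),
        "word_vocab": sorted(model.word_table.vocabulary, key=model.word_table.vocabulary.get),
        "lowercase_fallback": model.word_table.lowercase_fallback,
    }
    arrays = {k: v for k, v in model.trainable_arrays().items()}
    arrays["word_E"] = model.word_table.matrix
    np.savez(path, _meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> Model:
    with np.load(path) as data:
        try:
            meta = json.loads(bytes(data["_meta"]).decode())
        except KeyError:
            raise ValueError(f"{path}: not a model checkpoint (no metadata record)")
        if meta.get("version") != CHECKPOINT_VERSION:
            raise ValueError(
                f"{path}: checkpoint version {meta.get('version')!r}, "
                f"expected {CHECKPOINT_VERSION}"
            )
        cfg = ModelConfig(**{
            k: tuple(v) if isinstance(v, list) else v for k, v in meta["config"].items()
        })
        labels = LabelAlphabet(meta["entity_types"])
        alphabet = CharAlphabet("".join(meta["char_symbols"]), dim=cfg.char_dim)
        char_params = CharCNNParams(
            alphabet,
            data["char_E"].copy(),
            {k: data[f"char_W{k}"].copy() for k in cfg.char_kernels},
            {k: data[f"char_b{k}"].copy() for k in cfg.char_kernels},
        )
        vocab = {w: i for i, w in enumerate(meta["word_vocab"])}
        word_table = WordEmbeddingTable(vocab, data["word_E"].copy(), meta["lowercase_fallback"])
        pos_table = PosEmbeddingTable(meta["pos_tags"], dim=cfg.pos_dim)
        pos_table.matrix = data["pos_E"].copy()
        gram_params = NgramCNNParams(
            {j: data[f"gram_W{j}"].copy() for j in cfg.gram_kernels},
            {j: data[f"gram_b{j}"].copy() for j in cfg.gram_kernels},
            data["head_w1"].copy(),
            data["head_b1"].copy(),
            data["head_w2"].copy(),
            data["head_b2"].copy(),
        )
        transitions = data["T"].copy()
    return Model(cfg, labels, word_table, pos_table, char_params, gram_params, transitions)
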