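r"""Multi-width n-gram CNN encoder: the per-word local-context representation.

The encoder slides banks of convolution filters of several widths (kernel
sizes, default 1..10, 50 filters each) over the sentence's token vectors.
For kernel size j and a (padded) sentence of N positions this yields a
feature-map matrix of N - j + 1 rows — row m is the filter response over the
token window m..m+j-1.

A word's representation is built only from the *correlated* feature maps —
those whose window contains the word.  For word i (1-based) and kernel j the
correlated maps are the clamped range

    [max(1, i - j + 1), min(i, N - j + 1)]

For each filter, tanh is applied over the correlated rows and the maximum is
taken; concatenating over filters and then over kernel sizes (ascending)
gives a vector of length filters * |J|.  A two-layer fully connected head
(tanh in between) maps it to one raw score per IOB2 label; the CRF consumes
these unary scores, so no softmax is applied.

Sentences shorter than the largest kernel are right-padded with zero token
vectors; padded positions produce no output rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def _windows(X: np.ndarray, j: int) -> np.ndarray:
    n, D = X.shape
    if n < j:
        raise ValueError(f"{n} positions cannot host a size-{j} kernel")
    return np.lib.stride_tricks.sliding_window_view(X, (j, D)).reshape(n - j + 1, j * D)


@dataclass
class NgramCNNParams:
    """Filter banks (one per kernel size; ``weights[j]`` is (j*D, filters))
    plus the two-layer scoring head mapping the pooled representation to one
    unary score per label."""

    weights: dict[int, np.ndarray]
    biases: dict[int, np.ndarray]
    head_w1: np.ndarray  # (filters * |J|, hidden)
    head_b1: np.ndarray
    head_w2: np.ndarray  # (hidden, n_labels)
    head_b2: np.ndarray

    @property
    def kernel_sizes(self) -> tuple[int, ...]:
        return tuple(sorted(self.weights))

    @property
    def filters(self) -> int:
        return next(iter(self.weights.values())).shape[1]

    @property
    def representation_dim(self) -> int:
        return sum(w.shape[1] for w in self.weights.values())

    @property
    def n_labels(self) -> int:
        return self.head_w2.shape[1]

    @classmethod
    def create(
        cls,
        input_dim: int,
        n_labels: int,
        kernel_sizes: tuple[int, ...] = tuple(range(1, 11)),
        filters: int = 50,
        head_hidden: int = 100,
        rng: np.random.Generator | None = None,
    ) -> "NgramCNNParams":
        from .training import init_layer  # deferred: avoid import cycle

        if len(set(kernel_sizes)) != len(kernel_sizes) or not kernel_sizes:
            raise ValueError("kernel sizes must be a non-empty set of distinct widths")
        rng = rng if rng is not None else np.random.default_rng(0)
        weights, biases = {}, {}
        for j in sorted(kernel_sizes):
            weights[j], biases[j] = init_layer((j * input_dim, filters), rng)
        w1, b1 = init_layer((filters * len(kernel_sizes), head_hidden), rng)
        w2, b2 = init_layer((head_hidden, n_labels), rng)
        return cls(weights, biases, w1, b1, w2, b2)


def conv_maps(token_vectors: np.ndarray, params: NgramCNNParams, kernel: int) -> np.ndarray:
    """Feature maps for one kernel size: valid convolution, no stride.

    Returns (n - j + 1) x filters for n input positions.
    """
    return _windows(token_vectors, kernel) @ params.weights[kernel] + params.biases[kernel]


def correlated_indices(word_index: int, kernel: int, n: int) -> tuple[int, int]:
    """1-based inclusive range of kernel-``j`` feature maps whose window
    contains word ``i`` of an ``n``-position sequence:
    [max(1, i-j+1), min(i, n-j+1)].

    ``n`` is the padded length when the sentence is shorter than the kernel,
    so the range is never empty.
    """
    if not 1 <= word_index <= n:
        raise ValueError(f"word index {word_index} out of range 1..{n}")
    lo = max(1, word_index - kernel + 1)
    hi = min(word_index, n - kernel + 1)
    if hi < lo:
        raise ValueError(
            f"no size-{kernel} window exists in a sequence of {n} positions; "
            "pad the sentence to at least the kernel size"
        )
    return lo, hi


def word_representation(
    feature_maps: dict[int, np.ndarray], word_index: int, n: int
) -> np.ndarray:
    """Pooled local-context vector for one word (1-based index): per kernel
    size and filter, max of tanh over the correlated map rows; concatenated
    over filters then kernel sizes ascending."""
    parts = []
    for j in sorted(feature_maps):
        lo, hi = correlated_indices(word_index, j, n)
        parts.append(np.tanh(feature_maps[j][lo - 1 : hi]).max(axis=0))
    return np.concatenate(parts)


def unary_scores(representation: np.ndarray, params: NgramCNNParams) -> np.ndarray:
    """Two-layer head: affine -> tanh -> affine.  Raw scores, no softmax."""
    h = np.tanh(representation @ params.head_w1 + params.head_b1)
    return h @ params.head_w2 + params.head_b2


def sentence_unary_scores(token_vectors: np.ndarray, params: NgramCNNParams) -> np.ndarray:
    """Unary score matrix P (n x t) for a sentence given its token vectors.

    Pads with zero vectors up to the largest kernel size; P has one row per
    *true* token.
    """
    n = token_vectors.shape[0]
    J = params.kernel_sizes
    N = max(n, max(J))
    X = token_vectors
    if N > n:
        X = np.vstack([X, np.zeros((N - n, X.shape[1]))])
    maps = {j: conv_maps(X, params, j) for j in J}
    R = np.stack([word_representation(maps, i, N) for i in range(1, n + 1)])
    return unary_scores(R, params)
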