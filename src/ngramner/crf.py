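r"""Linear-chain conditional random field over label sequences.

A sentence of n words with t candidate labels is scored by a unary matrix
P (n x t, emitted by the upstream network) and a transition matrix T over the
t labels plus two distinguished states, start and end:

    s(x, y) = T[start, y_1] + sum_i T[y_i, y_{i+1}] + T[y_n, end]
            + sum_i P[i, y_i]

The conditional distribution is the softmax of s over all t^n label
sequences; the log-partition is computed by the forward recursion in
log-space, decoding by the Viterbi dynamic program, and the gradient of the
negative log-likelihood analytically from forward-backward marginals
(expected feature counts minus observed counts).

Conventions: label indices 0..t-1; ``T`` has shape (t+2, t+2) with
``start = t`` and ``end = t+1``; transitions *into* start and *out of* end
are fixed at -inf and never receive gradient.
"""

from __future__ import annotations

import numpy as np


def logsumexp(a: np.ndarray, axis: int | None = None) -> np.ndarray | float:
    """log(sum(exp(a))) computed stably; tolerant of -inf entries."""
    m = np.max(a, axis=axis, keepdims=True)
    m = np.where(np.isfinite(m), m, 0.0)
    with np.errstate(divide="ignore"):
        s = np.log(np.sum(np.exp(a - m), axis=axis))
    if axis is None:
        return float(m.reshape(()) + s)
    return np.squeeze(m, axis=axis) + s


def start_index(n_labels: int) -> int:
    return n_labels


def end_index(n_labels: int) -> int:
    return n_labels + 1


def make_transitions(n_labels: int, init: np.ndarray | None = None) -> np.ndarray:
    """Fresh (t+2)x(t+2) transition matrix; forbidden entries at -inf."""
    T = np.zeros((n_labels + 2, n_labels + 2)) if init is None else init.copy()
    T[:, start_index(n_labels)] = -np.inf
    T[end_index(n_labels), :] = -np.inf
    return T


def _check(P: np.ndarray, T: np.ndarray) -> tuple[int, int]:
    n, t = P.shape
    if n < 1:
        raise ValueError("need at least one word")
    if T.shape != (t + 2, t + 2):
        raise ValueError(f"transition matrix {T.shape} does not match t={t}")
    return n, t


def sequence_score(P: np.ndarray, T: np.ndarray, y: np.ndarray) -> float:
    """Score of one label sequence, including start/end transitions."""
    n, t = _check(P, T)
    y = np.asarray(y, dtype=int)
    if y.shape != (n,):
        raise ValueError(f"label sequence length {y.shape} does not match n={n}")
    if y.min() < 0 or y.max() >= t:
        raise ValueError("label index out of alphabet")
    score = T[start_index(t), y[0]] + T[y[-1], end_index(t)]
    score += T[y[:-1], y[1:]].sum()
    score += P[np.arange(n), y].sum()
    return float(score)


def _forward_alphas(P: np.ndarray, T: np.ndarray) -> np.ndarray:
    """log alpha[i, y] = log sum over prefixes ending in label y at word i."""
    n, t = P.shape
    alphas = np.empty((n, t))
    alphas[0] = T[start_index(t), :t] + P[0]
    for i in range(1, n):
        alphas[i] = logsumexp(alphas[i - 1][:, None] + T[:t, :t], axis=0) + P[i]
    return alphas


def _backward_betas(P: np.ndarray, T: np.ndarray) -> np.ndarray:
    """log beta[i, y] = log sum over suffixes given label y at word i."""
    n, t = P.shape
    betas = np.empty((n, t))
    betas[-1] = T[:t, end_index(t)]
    for i in range(n - 2, -1, -1):
        betas[i] = logsumexp(T[:t, :t] + (P[i + 1] + betas[i + 1])[None, :], axis=1)
    return betas


def log_partition(P: np.ndarray, T: np.ndarray) -> float:
    """log of the sum of exp(score) over all t^n label sequences."""
    n, t = _check(P, T)
    alphas = _forward_alphas(P, T)
    return float(logsumexp(alphas[-1] + T[:t, end_index(t)]))


def sequence_probability(P: np.ndarray, T: np.ndarray, y: np.ndarray) -> float:
    """p(y | x) = exp(s(x, y) - log Z)."""
    return float(np.exp(sequence_score(P, T, y) - log_partition(P, T)))


def neg_log_likelihood(P: np.ndarray, T: np.ndarray, y: np.ndarray) -> float:
    """-log p(y_gold | x); non-negative up to floating-point error."""
    return log_partition(P, T) - sequence_score(P, T, y)


def nll_and_gradients(
    P: np.ndarray, T: np.ndarray, y: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """NLL and its gradients with respect to P and T.

    dNLL/dP[i, l]   = p(y_i = l | x)           - 1[y_i = l]
    dNLL/dT[a, b]   = E[# transitions a -> b]  - observed count,
    including the start->y_1 and y_n->end transitions.  Forbidden entries of
    T get zero gradient.
    """
    n, t = _check(P, T)
    y = np.asarray(y, dtype=int)
    s, e = start_index(t), end_index(t)

    alphas = _forward_alphas(P, T)
    betas = _backward_betas(P, T)
    logZ = float(logsumexp(alphas[-1] + T[:t, e]))

    # unary marginals
    gamma = np.exp(alphas + betas - logZ)  # (n, t)

    dP = gamma.copy()
    dP[np.arange(n), y] -= 1.0

    dT = np.zeros_like(T)
    # interior pairwise marginals
    for i in range(n - 1):
        xi = np.exp(
            alphas[i][:, None] + T[:t, :t] + (P[i + 1] + betas[i + 1])[None, :] - logZ
        )
        dT[:t, :t] += xi
    np.subtract.at(dT, (y[:-1], y[1:]), 1.0)
    # boundary transitions
    dT[s, :t] += gamma[0]
    dT[s, y[0]] -= 1.0
    dT[:t, e] += gamma[-1]
    dT[y[-1], e] -= 1.0

    nll = logZ - sequence_score(P, T, y)
    return nll, dP, dT


def viterbi_decode(P: np.ndarray, T: np.ndarray) -> tuple[list[int], float]:
    """Maximum-score label sequence and its score.

    Ties are broken toward the lowest label index at every backtrack step.
    """
    n, t = _check(P, T)
    s, e = start_index(t), end_index(t)
    delta = T[s, :t] + P[0]
    back = np.empty((n, t), dtype=int)
    for i in range(1, n):
        cand = delta[:, None] + T[:t, :t]  # cand[a, b]
        back[i] = np.argmax(cand, axis=0)  # argmax -> lowest index on ties
        delta = cand[back[i], np.arange(t)] + P[i]
    final = delta + T[:t, e]
    last = int(np.argmax(final))
    score = float(final[last])
    path = [last]
    for i in range(n - 1, 0, -1):
        path.append(int(back[i, path[-1]]))
    path.reverse()
    return path, score
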