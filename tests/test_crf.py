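"""Linear-chain CRF: scoring, partition, probabilities, Viterbi, gradients.

The oracle throughout is exhaustive enumeration of all t^n label sequences
with literal re-summation of the score — independent of the forward/Viterbi
recursions it checks.
"""

import itertools

import numpy as np
import pytest

from ngramner.crf import (
    end_index,
    log_partition,
    make_transitions,
    neg_log_likelihood,
    nll_and_gradients,
    sequence_probability,
    sequence_score,
    start_index,
    viterbi_decode,
)


def enumerate_scores(P, T):
    """Literal score of every possible label sequence."""
    n, t = P.shape
    out = {}
    for y in itertools.product(range(t), repeat=n):
        s = T[start_index(t), y[0]] + T[y[-1], end_index(t)]
        for a, b in zip(y, y[1:]):
            s += T[a, b]
        for i, lab in enumerate(y):
            s += P[i, lab]
        out[y] = s
    return out


def random_instance(rng, n=None, t=None, scale=3.0):
    n = n if n is not None else int(rng.integers(1, 7))
    t = t if t is not None else int(rng.integers(2, 5))
    P = rng.normal(scale=scale, size=(n, t))
    T = make_transitions(t)
    T[: t + 1, :] += rng.normal(scale=scale, size=(t + 1, t + 2))
    T[:, start_index(t)] = -np.inf
    T[end_index(t), :] = -np.inf
    return P, T


def test_make_transitions_forbidden_entries():
    T = make_transitions(3)
    assert np.all(np.isinf(T[:, start_index(3)]))
    assert np.all(np.isinf(T[end_index(3), :]))
    assert np.all(T[:4, [0, 1, 2, 4]] == 0)


# ---------------------------------------------------------------------------
# sequence score
# ---------------------------------------------------------------------------

def test_sequence_score_zero_params_is_zero():
    P = np.zeros((4, 3))
    T = make_transitions(3)
    for y in itertools.product(range(3), repeat=4):
        assert sequence_score(P, T, np.array(y)) == 0.0


def test_sequence_score_single_word_hand_value():
    P = np.array([[1.0, 2.0]])
    T = make_transitions(2)
    assert sequence_score(P, T, [0]) == 1.0
    assert sequence_score(P, T, [1]) == 2.0


def test_sequence_score_matches_literal_summation(rng):
    for _ in range(20):
        P, T = random_instance(rng)
        table = enumerate_scores(P, T)
        for y, expected in table.items():
            assert sequence_score(P, T, np.array(y)) == pytest.approx(expected)


def test_sequence_score_length_mismatch():
    P = np.zeros((3, 2))
    with pytest.raises(ValueError):
        sequence_score(P, make_transitions(2), [0, 1])


# ---------------------------------------------------------------------------
# partition function
# ---------------------------------------------------------------------------

def test_log_partition_two_equal_sequences():
    P = np.zeros((1, 2))
    assert log_partition(P, make_transitions(2)) == pytest.approx(np.log(2.0))


def test_log_partition_matches_enumeration(rng):
    for _ in range(30):
        P, T = random_instance(rng)
        expected = np.logaddexp.reduce(list(enumerate_scores(P, T).values()))
        assert log_partition(P, T) == pytest.approx(expected, abs=1e-8)


def test_log_partition_row_shift_identity(rng):
    P, T = random_instance(rng, n=4, t=3)
    base = log_partition(P, T)
    P2 = P.copy()
    P2[2] += 7.5
    assert log_partition(P2, T) == pytest.approx(base + 7.5)


def test_log_partition_stable_at_large_scores():
    P = np.full((5, 3), 1e3)
    T = make_transitions(3)
    got = log_partition(P, T)
    assert np.isfinite(got)
    assert got == pytest.approx(5e3 + 5 * np.log(3.0))


# ---------------------------------------------------------------------------
# probabilities and NLL
# ---------------------------------------------------------------------------

def test_probabilities_sum_to_one(rng):
    for _ in range(10):
        P, T = random_instance(rng, n=int(rng.integers(1, 6)), t=3)
        total = sum(
            sequence_probability(P, T, np.array(y)) for y in enumerate_scores(P, T)
        )
        assert total == pytest.approx(1.0, abs=1e-8)


def test_uniform_scores_give_uniform_probability():
    P = np.zeros((3, 2))
    T = make_transitions(2)
    for y in itertools.product(range(2), repeat=3):
        assert sequence_probability(P, T, np.array(y)) == pytest.approx(1 / 8)


def test_nll_uniform_closed_form():
    P = np.zeros((2, 2))
    assert neg_log_likelihood(P, make_transitions(2), [0, 1]) == pytest.approx(2 * np.log(2))


def test_nll_vanishes_for_peaked_scores():
    P = np.array([[50.0, 0.0], [0.0, 50.0]])
    assert neg_log_likelihood(P, make_transitions(2), [0, 1]) < 1e-8


def test_nll_nonnegative(rng):
    for _ in range(25):
        P, T = random_instance(rng)
        y = rng.integers(P.shape[1], size=P.shape[0])
        assert neg_log_likelihood(P, T, y) >= -1e-10


def test_global_shift_leaves_distribution_unchanged(rng):
    P, T = random_instance(rng, n=4, t=3)
    y = np.array([0, 2, 1, 0])
    p1 = sequence_probability(P, T, y)
    p2 = sequence_probability(P + 11.0, T, y)
    assert p1 == pytest.approx(p2)
    assert viterbi_decode(P, T)[0] == viterbi_decode(P + 11.0, T)[0]


# ---------------------------------------------------------------------------
# Viterbi
# ---------------------------------------------------------------------------

def test_viterbi_hand_example():
    P = np.array([[5.0, 0.0], [0.0, 5.0]])
    path, score = viterbi_decode(P, make_transitions(2))
    assert path == [0, 1]
    assert score == 10.0


def test_viterbi_single_word():
    P = np.array([[0.3, 1.2, -4.0]])
    T = make_transitions(3)
    T[start_index(3), :3] = [0.0, -5.0, 0.0]
    path, score = viterbi_decode(P, T)
    assert path == [0]  # start transition outweighs the unary
    assert score == pytest.approx(0.3)


def test_viterbi_matches_enumeration(rng):
    for _ in range(40):
        P, T = random_instance(rng)
        table = enumerate_scores(P, T)
        best = max(table.values())
        path, score = viterbi_decode(P, T)
        assert score == pytest.approx(best, abs=1e-8)
        assert table[tuple(path)] == pytest.approx(best, abs=1e-8)
        # unique optimum -> identical path
        sorted_scores = sorted(table.values(), reverse=True)
        if len(sorted_scores) < 2 or sorted_scores[0] - sorted_scores[1] > 1e-9:
            assert tuple(path) == max(table, key=table.get)


def test_viterbi_tie_break_lowest_index():
    P = np.zeros((3, 3))
    path, score = viterbi_decode(P, make_transitions(3))
    assert path == [0, 0, 0] and score == 0.0


def test_viterbi_path_is_most_probable(rng):
    P, T = random_instance(rng, n=4, t=3)
    path, _ = viterbi_decode(P, T)
    p_best = sequence_probability(P, T, np.array(path))
    for y in enumerate_scores(P, T):
        assert p_best >= sequence_probability(P, T, np.array(y)) - 1e-12


# ---------------------------------------------------------------------------
# gradients
# ---------------------------------------------------------------------------

def test_nll_gradients_match_finite_differences(rng):
    eps = 1e-6
    for _ in range(5):
        P, T = random_instance(rng, n=4, t=3, scale=1.0)
        y = rng.integers(3, size=4)
        nll, dP, dT = nll_and_gradients(P, T, y)
        assert nll == pytest.approx(neg_log_likelihood(P, T, y))
        for idx in np.ndindex(P.shape):
            P[idx] += eps
            up = neg_log_likelihood(P, T, y)
            P[idx] -= 2 * eps
            down = neg_log_likelihood(P, T, y)
            P[idx] += eps
            assert dP[idx] == pytest.approx((up - down) / (2 * eps), abs=1e-4)
        for idx in np.ndindex(T.shape):
            if not np.isfinite(T[idx]):
                assert dT[idx] == 0.0
                continue
            T[idx] += eps
            up = neg_log_likelihood(P, T, y)
            T[idx] -= 2 * eps
            down = neg_log_likelihood(P, T, y)
            T[idx] += eps
            assert dT[idx] == pytest.approx((up - down) / (2 * eps), abs=1e-4)
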