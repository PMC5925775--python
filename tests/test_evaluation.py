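"""Chunk-level P/R/F1, micro-averaging, and the error categorizer."""

import numpy as np
import pytest

from ngramner.corpus import Chunk, LabelAlphabet, Sentence, Token, encode_iob2
from ngramner.evaluation import (
    ErrorRecord,
    error_report,
    evaluate_chunks,
    evaluate_corpus,
    match_chunks,
    prf,
)

G = lambda s, e: Chunk("Gene", s, e)
D = lambda s, e: Chunk("Dis", s, e)


# ---------------------------------------------------------------------------
# counting and the P/R/F1 formulas
# ---------------------------------------------------------------------------

def test_match_chunks_examples():
    three = [G(0, 2), G(3, 4), D(5, 7)]
    assert match_chunks(three, three) == (3, 0, 0)
    # boundary error is one FP and one FN under exact matching
    assert match_chunks([G(0, 3)], [G(0, 2)]) == (0, 1, 1)
    assert match_chunks([G(0, 2), D(3, 4)], [G(0, 2)]) == (1, 0, 1)


def test_match_chunks_count_identities(rng):
    for _ in range(50):
        gold = {Chunk("Gene", s, s + 1) for s in rng.choice(30, size=5, replace=False)}
        pred = {Chunk("Gene", s, s + 1) for s in rng.choice(30, size=7, replace=False)}
        tp, fp, fn = match_chunks(sorted(gold, key=lambda c: c.start),
                                  sorted(pred, key=lambda c: c.start))
        assert tp + fp == len(pred)
        assert tp + fn == len(gold)


@pytest.mark.parametrize(
    "counts, expected",
    [((3, 0, 0), (1.0, 1.0, 1.0)), ((1, 1, 1), (0.5, 0.5, 0.5)), ((0, 0, 5), (0, 0, 0))],
)
def test_prf_values(counts, expected):
    assert prf(*counts) == pytest.approx(expected)


def test_f1_bounded_by_max_of_p_and_r():
    for tp, fp, fn in [(3, 1, 5), (2, 8, 1), (1, 1, 1), (0, 3, 2)]:
        p, r, f1 = prf(tp, fp, fn)
        assert f1 <= max(p, r) + 1e-12
        # harmonic mean is symmetric in p and r
        p2, r2, f2 = prf(tp, fn, fp)
        assert f2 == pytest.approx(f1)


# ---------------------------------------------------------------------------
# corpus-level evaluation
# ---------------------------------------------------------------------------

def _labeled(length, chunks):
    labels = encode_iob2(length, chunks)
    return Sentence([Token(f"w{i}", gold_label=l) for i, l in enumerate(labels)])


def test_perfect_predictions_score_one(small_corpus):
    sentences, _ = small_corpus
    res = evaluate_corpus(sentences, [s.gold_labels for s in sentences])
    assert res.overall.f1 == 1.0
    assert res.overall.fp == res.overall.fn == 0


def test_all_outside_predictions(small_corpus):
    sentences, chunks = small_corpus
    k = sum(len(c) for c in chunks)
    res = evaluate_corpus(sentences, [["O"] * len(s) for s in sentences])
    assert (res.overall.precision, res.overall.recall, res.overall.f1) == (0, 0, 0)
    assert res.overall.fn == k


def test_hand_built_fixture_counts():
    sents = [
        _labeled(5, [G(0, 2)]),          # predicted with a boundary error
        _labeled(4, [D(1, 2)]),          # missed entirely
        _labeled(6, [G(2, 4), D(5, 6)]), # both exactly right
    ]
    preds = [
        encode_iob2(5, [G(0, 3)]),
        ["O"] * 4,
        encode_iob2(6, [G(2, 4), D(5, 6)]),
    ]
    res = evaluate_corpus(sents, preds)
    assert (res.overall.tp, res.overall.fp, res.overall.fn) == (2, 1, 2)
    assert res.per_type["Gene"].tp == 1 and res.per_type["Gene"].fp == 1
    assert res.per_type["Dis"].fn == 1
    # micro-average: overall counts are the per-type sums
    assert res.overall.tp == sum(s.tp for s in res.per_type.values())
    assert res.overall.fp == sum(s.fp for s in res.per_type.values())
    assert res.overall.fn == sum(s.fn for s in res.per_type.values())


def test_evaluate_corpus_length_mismatch_names_sentence(small_corpus):
    sentences, _ = small_corpus
    preds = [s.gold_labels for s in sentences]
    preds[1] = preds[1][:-1]
    with pytest.raises(Exception, match=sentences[1].id):
        evaluate_corpus(sentences, preds)


def test_jsonl_report_rows(small_corpus):
    sentences, _ = small_corpus
    res = evaluate_corpus(sentences, [s.gold_labels for s in sentences])
    rows = res.to_records()
    assert rows[0]["type"] == "overall"
    assert all({"tp", "fp", "fn", "precision", "recall", "f1"} <= set(r) for r in rows)


# ---------------------------------------------------------------------------
# independent cross-check
# ---------------------------------------------------------------------------

def reference_prf(gold_labels, pred_labels):
    """Independent oracle: scan-based span extraction + direct counting,
    coded separately from the package's incremental decoder."""

    def spans(labels):
        found = set()
        i = 0
        while i < len(labels):
            lab = labels[i]
            if lab == "O":
                i += 1
                continue
            t = lab[2:]
            starts = lab.startswith("B-") or (
                lab.startswith("I-") and (i == 0 or labels[i - 1][2:] != t
                                          or labels[i - 1] == "O")
            )
            if not starts:
                i += 1
                continue
            j = i + 1
            while j < len(labels) and labels[j] == f"I-{t}":
                j += 1
            found.add((t, i, j))
            i = j
        return found

    tp = fp = fn = 0
    for g, p in zip(gold_labels, pred_labels):
        gs, ps = spans(g), spans(p)
        tp += len(gs & ps)
        fp += len(ps - gs)
        fn += len(gs - ps)
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    f = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f


def random_label_corpus(rng, n_sentences=8):
    labels = ["O", "B-Gene", "I-Gene", "B-Dis", "I-Dis"]
    corpus = []
    for _ in range(n_sentences):
        n = int(rng.integers(1, 15))
        corpus.append([labels[i] for i in rng.integers(len(labels), size=n)])
    return corpus


def test_agreement_with_independent_reference(rng):
    for _ in range(100):
        gold = random_label_corpus(rng)
        pred = [
            [lab if rng.random() < 0.7 else "O" for lab in sent] for sent in gold
        ]
        sents = [
            Sentence([Token(f"w{i}", gold_label=l) for i, l in enumerate(g)])
            for g in gold
        ]
        res = evaluate_corpus(sents, pred)
        ref = reference_prf(gold, pred)
        assert (res.overall.precision, res.overall.recall, res.overall.f1) == \
            pytest.approx(ref)


# ---------------------------------------------------------------------------
# error categorization
# ---------------------------------------------------------------------------

def test_error_report_empty_and_disjoint():
    assert error_report([], []) == []
    recs = error_report([], [G(2, 3)])
    assert [r.category for r in recs] == ["false_positive"]
    recs = error_report([G(0, 1)], [])
    assert [r.category for r in recs] == ["false_negative"]


def test_error_report_split_with_type_mismatch():
    recs = error_report(
        [Chunk("Prot", 0, 4)], [Chunk("DNA", 0, 3), Chunk("Prot", 3, 4)]
    )
    assert len(recs) == 1
    assert recs[0].category == "split"
    assert recs[0].type_mismatch


def test_error_report_boundary_merge_type():
    assert error_report([G(0, 3)], [G(0, 2)])[0].category == "boundary"
    assert error_report([G(0, 2)], [D(0, 2)])[0].category == "type"
    merge = error_report([G(0, 2), G(3, 5)], [G(0, 5)])
    assert [r.category for r in merge] == ["merge"]
    assert not merge[0].type_mismatch


def test_error_report_exact_matches_are_silent():
    assert error_report([G(0, 2), D(3, 4)], [G(0, 2), D(3, 4)]) == []
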