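"""Chunk-level evaluation: precision, recall and F1 over entity spans.

A predicted chunk counts as a true positive only when a gold chunk with the
same type, start and end exists (exact-span, exact-type matching).  Scores
are micro-averaged: TP/FP/FN are pooled over the corpus (and over types for
the overall row), then

    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = 2 * precision * recall / (precision + recall)

with the convention that an empty denominator gives 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

from .corpus import Chunk, Sentence, ValidationError, decode_chunks


@dataclass(frozen=True)
class Scores:
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0

    def __add__(self, other: "Scores") -> "Scores":
        return Scores(self.tp + other.tp, self.fp + other.fp, self.fn + other.fn)


@dataclass
class EvalResult:
    overall: Scores
    per_type: dict[str, Scores]

    def to_records(self) -> list[dict]:
        rows = [{"type": "overall", **_row(self.overall)}]
        rows += [{"type": t, **_row(s)} for t, s in sorted(self.per_type.items())]
        return rows

    def to_jsonl(self) -> str:
        return "\n".join(json.dumps(r) for r in self.to_records()) + "\n"

    def __str__(self) -> str:
        lines = [f"{'type':<12} {'tp':>5} {'fp':>5} {'fn':>5} {'prec':>7} {'rec':>7} {'f1':>7}"]
        for r in self.to_records():
            lines.append(
                f"{r['type']:<12} {r['tp']:>5} {r['fp']:>5} {r['fn']:>5} "
                f"{r['precision']:>7.4f} {r['recall']:>7.4f} {r['f1']:>7.4f}"
            )
        return "\n".join(lines)


def _row(s: Scores) -> dict:
    return {
        "tp": s.tp, "fp": s.fp, "fn": s.fn,
        "precision": s.precision, "recall": s.recall, "f1": s.f1,
    }


def match_chunks(gold: Sequence[Chunk], pred: Sequence[Chunk]) -> tuple[int, int, int]:
    """Exact-match counts: (tp, fp, fn).  A boundary or type error costs one
    FP *and* one FN."""
    gold_set, pred_set = set(gold), set(pred)
    tp = len(gold_set & pred_set)
    return tp, len(pred_set) - tp, len(gold_set) - tp


def prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    """Precision, recall, F1 from pooled counts (0 on empty denominators)."""
    s = Scores(tp, fp, fn)
    return s.precision, s.recall, s.f1


def evaluate_chunks(
    gold: Sequence[Sequence[Chunk]], pred: Sequence[Sequence[Chunk]]
) -> EvalResult:
    """Micro-averaged evaluation over per-sentence chunk lists."""
    if len(gold) != len(pred):
        raise ValidationError(f"{len(gold)} gold vs {len(pred)} predicted sentences")
    per_type: dict[str, Scores] = {}
    for g_sent, p_sent in zip(gold, pred):
        types = {c.entity_type for c in g_sent} | {c.entity_type for c in p_sent}
        for t in types:
            tp, fp, fn = match_chunks(
                [c for c in g_sent if c.entity_type == t],
                [c for c in p_sent if c.entity_type == t],
            )
            per_type[t] = per_type.get(t, Scores(0, 0, 0)) + Scores(tp, fp, fn)
    overall = sum(per_type.values(), Scores(0, 0, 0))
    return EvalResult(overall, per_type)


def evaluate_corpus(
    sentences: Sequence[Sentence],
    predicted: Sequence[Sequence[str]],
    repair: str = "conll",
) -> EvalResult:
    """Decode gold and predicted IOB2 label streams to chunks and score them."""
    if len(sentences) != len(predicted):
        raise ValidationError(f"{len(sentences)} sentences vs {len(predicted)} predictions")
    gold, pred = [], []
    for sent, labels in zip(sentences, predicted):
        if len(labels) != len(sent):
            raise ValidationError(
                f"sentence {sent.id!r}: {len(labels)} predicted labels for {len(sent)} tokens"
            )
        gold.append(decode_chunks(sent.gold_labels, repair=repair))
        pred.append(decode_chunks(list(labels), repair=repair))
    return evaluate_chunks(gold, pred)


# ---------------------------------------------------------------------------
# error categorization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ErrorRecord:
    """One mismatch between gold and predicted chunks of a sentence.

    category: false_negative | false_positive | boundary | split | merge | type
    ``type_mismatch`` flags composite errors (e.g. a split whose fragments
    also change type).
    """

    category: str
    gold: tuple[Chunk, ...]
    pred: tuple[Chunk, ...]
    type_mismatch: bool = False


def error_report(
    gold: Sequence[Chunk], pred: Sequence[Chunk]
) -> list[ErrorRecord]:
    """Classify every non-exact match between two chunk lists of one sentence."""
    gold = sorted(gold, key=lambda c: (c.start, c.end))
    pred = sorted(pred, key=lambda c: (c.start, c.end))
    matched_g = {g for g in gold if g in set(pred)}
    matched_p = {p for p in pred if p in set(gold)}
    rest_g = [g for g in gold if g not in matched_g]
    rest_p = [p for p in pred if p not in matched_p]

    records: list[ErrorRecord] = []
    used_p: set[Chunk] = set()
    used_g: set[Chunk] = set()
    for g in rest_g:
        if g in used_g:
            continue
        overlapping = [p for p in rest_p if p not in used_p and g.overlaps(p)]
        if not overlapping:
            records.append(ErrorRecord("false_negative", (g,), ()))
            used_g.add(g)
            continue
        mism = any(p.entity_type != g.entity_type for p in overlapping)
        if len(overlapping) >= 2:
            records.append(ErrorRecord("split", (g,), tuple(overlapping), mism))
            used_p.update(overlapping)
            used_g.add(g)
            continue
        p = overlapping[0]
        partners = [g2 for g2 in rest_g if g2 not in used_g and g2.overlaps(p)]
        if len(partners) >= 2:
            mism = any(g2.entity_type != p.entity_type for g2 in partners)
            records.append(ErrorRecord("merge", tuple(partners), (p,), mism))
            used_g.update(partners)
            used_p.add(p)
            continue
        if (p.start, p.end) == (g.start, g.end):
            records.append(ErrorRecord("type", (g,), (p,), True))
        else:
            records.append(ErrorRecord("boundary", (g,), (p,), p.entity_type != g.entity_type))
        used_p.add(p)
        used_g.add(g)
    for p in rest_p:
        if p not in used_p:
            records.append(ErrorRecord("false_positive", (), (p,)))
    return records
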