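"""Corpus representation: tokens, sentences, entity chunks, IOB2 codec, CoNLL-style IO.

The unit of annotation is the *chunk*: a maximal typed span of consecutive
tokens (e.g. a gene mention).  Chunks are stored 0-based, half-open, in token
coordinates, and serialized per token with the IOB2 scheme: ``B-t`` opens an
entity of type ``t``, ``I-t`` continues it, ``O`` marks outside tokens.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

_LABEL_RE = re.compile(r"^(O|[BI]-\S+)$")


class ValidationError(ValueError):
    """An object violates a corpus invariant (bad chunk, bad label, misalignment)."""


class ParseError(ValueError):
    """A file could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"line {line}: {message}" if line is not None else message)


@dataclass(frozen=True)
class Token:
    """A single token: surface form, optional POS tag, optional gold IOB2 label."""

    surface: str
    pos: str | None = None
    gold_label: str | None = None

    def __post_init__(self):
        if not self.surface:
            raise ValidationError("token surface must be non-empty")
        if self.gold_label is not None and not _LABEL_RE.match(self.gold_label):
            raise ValidationError(
                f"gold label {self.gold_label!r} does not match O | B-<type> | I-<type>"
            )


@dataclass
class Sentence:
    """An ordered token sequence with an opaque identifier.

    Either every token carries a gold label or none does.
    """

    tokens: list[Token]
    id: str = ""

    def __post_init__(self):
        if len(self.tokens) == 0:
            raise ValidationError(f"sentence {self.id!r} is empty")
        labeled = [t.gold_label is not None for t in self.tokens]
        if any(labeled) and not all(labeled):
            raise ValidationError(f"sentence {self.id!r} mixes labeled and unlabeled tokens")

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def is_labeled(self) -> bool:
        return self.tokens[0].gold_label is not None

    @property
    def surfaces(self) -> list[str]:
        return [t.surface for t in self.tokens]

    @property
    def gold_labels(self) -> list[str]:
        if not self.is_labeled:
            raise ValidationError(f"sentence {self.id!r} has no gold labels")
        return [t.gold_label for t in self.tokens]  # type: ignore[misc]

    def gold_chunks(self) -> list["Chunk"]:
        return decode_chunks(self.gold_labels, repair="conll")


@dataclass(frozen=True)
class Chunk:
    """A typed entity span: 0-based token indices, half-open [start, end)."""

    entity_type: str
    start: int
    end: int

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValidationError(f"chunk {self} must satisfy 0 <= start < end")

    def overlaps(self, other: "Chunk") -> bool:
        return self.start < other.end and other.start < self.end


class LabelAlphabet:
    """Ordered IOB2 label set with a contiguous label<->integer index map.

    ``O`` is always present at index 0 and every ``I-t`` is accompanied by
    ``B-t``.  Built canonically from the set of entity types: labels are
    ``[O, B-t1, I-t1, B-t2, I-t2, ...]``.
    """

    def __init__(self, entity_types: Sequence[str]):
        seen: list[str] = []
        for t in entity_types:
            if t not in seen:
                seen.append(t)
        self.entity_types: tuple[str, ...] = tuple(seen)
        self.labels: tuple[str, ...] = ("O",) + tuple(
            lab for t in self.entity_types for lab in (f"B-{t}", f"I-{t}")
        )
        self._index = {lab: i for i, lab in enumerate(self.labels)}

    @classmethod
    def from_labels(cls, labels: Iterable[str]) -> "LabelAlphabet":
        types: list[str] = []
        for lab in labels:
            if not _LABEL_RE.match(lab):
                raise ValidationError(f"not an IOB2 label: {lab!r}")
            if lab != "O":
                t = lab[2:]
                if t not in types:
                    types.append(t)
        return cls(types)

    @classmethod
    def from_corpus(cls, sentences: Iterable[Sentence]) -> "LabelAlphabet":
        return cls.from_labels(
            lab for s in sentences if s.is_labeled for lab in s.gold_labels
        )

    def __len__(self) -> int:
        return len(self.labels)

    def __contains__(self, label: str) -> bool:
        return label in self._index

    def __eq__(self, other) -> bool:
        return isinstance(other, LabelAlphabet) and self.labels == other.labels

    def index(self, label: str) -> int:
        try:
            return self._index[label]
        except KeyError:
            raise ValidationError(f"label {label!r} not in alphabet {self.labels}") from None

    def label(self, i: int) -> str:
        return self.labels[i]

    def encode(self, labels: Sequence[str]) -> list[int]:
        return [self.index(lab) for lab in labels]

    def decode(self, indices: Sequence[int]) -> list[str]:
        return [self.labels[i] for i in indices]


def _check_chunks(sentence_length: int, chunks: Sequence[Chunk]) -> list[Chunk]:
    ordered = sorted(chunks, key=lambda c: (c.start, c.end))
    prev_end = 0
    prev: Chunk | None = None
    for c in ordered:
        if c.end > sentence_length:
            raise ValidationError(f"chunk {c} exceeds sentence length {sentence_length}")
        if prev is not None and c.start < prev_end:
            raise ValidationError(f"chunk {c} overlaps {prev}")
        prev_end, prev = c.end, c
    return ordered


def encode_iob2(sentence_length: int, chunks: Sequence[Chunk]) -> list[str]:
    """Render chunks as one IOB2 label per token position.

    The chunk's first token gets ``B-type``, the rest ``I-type``, everything
    else ``O``.  Chunks may be given in any order but must be in-range and
    non-overlapping.
    """
    labels = ["O"] * sentence_length
    for c in _check_chunks(sentence_length, chunks):
        labels[c.start] = f"B-{c.entity_type}"
        for i in range(c.start + 1, c.end):
            labels[i] = f"I-{c.entity_type}"
    return labels


def decode_chunks(labels: Sequence[str], repair: str = "conll") -> list[Chunk]:
    """Extract typed chunks from an IOB2 label sequence.

    ``repair="conll"`` follows the conventional chunking-evaluation repair:
    an ``I-t`` that does not continue a chunk of type ``t`` opens a new chunk
    of type ``t``.  ``repair="strict"`` raises on such sequences instead.
    """
    if repair not in ("conll", "strict"):
        raise ValueError(f"unknown repair policy {repair!r}")
    chunks: list[Chunk] = []
    open_type: str | None = None
    open_start = 0

    def close(end: int):
        nonlocal open_type
        if open_type is not None:
            chunks.append(Chunk(open_type, open_start, end))
            open_type = None

    for i, lab in enumerate(labels):
        if not _LABEL_RE.match(lab):
            raise ValidationError(f"position {i}: not an IOB2 label: {lab!r}")
        if lab == "O":
            close(i)
        elif lab.startswith("B-"):
            close(i)
            open_type, open_start = lab[2:], i
        else:  # I-t
            t = lab[2:]
            if open_type == t:
                continue
            if repair == "strict":
                raise ValidationError(
                    f"position {i}: illegal {lab} after "
                    f"{'chunk of type ' + open_type if open_type else 'O'}"
                )
            close(i)
            open_type, open_start = t, i
    close(len(labels))
    return chunks


# ---------------------------------------------------------------------------
# CoNLL-style token-per-line files
# ---------------------------------------------------------------------------

def read_conll(
    path: str | Path,
    surface_col: int = 0,
    pos_col: int | None = 1,
    label_col: int | None = 2,
) -> list[Sentence]:
    """Read a token-per-line file: whitespace-separated columns, blank lines
    between sentences, ``-DOCSTART-`` lines skipped.

    Column indices select which field holds the surface / POS / gold label;
    pass ``None`` for absent columns.  A POS field of ``-`` reads as missing.
    """
    sentences: list[Sentence] = []
    tokens: list[Token] = []
    n_cols_needed = max(c for c in (surface_col, pos_col, label_col) if c is not None) + 1

    def flush():
        if tokens:
            sentences.append(Sentence(list(tokens), id=str(len(sentences))))
            tokens.clear()

    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                flush()
                continue
            if line.startswith("-DOCSTART-"):
                continue
            cols = line.split()
            if len(cols) < n_cols_needed:
                raise ParseError(
                    f"expected at least {n_cols_needed} columns, got {len(cols)}: {line!r}",
                    line=lineno,
                )
            pos = cols[pos_col] if pos_col is not None else None
            if pos == "-":
                pos = None
            label = cols[label_col] if label_col is not None else None
            try:
                tokens.append(Token(cols[surface_col], pos=pos, gold_label=label))
            except ValidationError as e:
                raise ParseError(str(e), line=lineno) from e
    flush()
    return sentences


def write_conll(
    sentences: Sequence[Sentence],
    path: str | Path,
    predicted: Sequence[Sequence[str]] | None = None,
) -> None:
    """Write sentences token-per-line: surface, POS (``-`` if absent), gold
    label (if the sentence is labeled), then the predicted label (if given).

    Gold precedes predicted.  ``read_conll(write_conll(x)) == x``.
    """
    if predicted is not None and len(predicted) != len(sentences):
        raise ValidationError(
            f"{len(predicted)} prediction rows for {len(sentences)} sentences"
        )
    with open(path, "w", encoding="utf-8") as fh:
        for k, sent in enumerate(sentences):
            pred = predicted[k] if predicted is not None else None
            if pred is not None and len(pred) != len(sent):
                raise ValidationError(
                    f"sentence {sent.id!r}: {len(pred)} predicted labels "
                    f"for {len(sent)} tokens"
                )
            for i, tok in enumerate(sent.tokens):
                cols = [tok.surface, tok.pos if tok.pos is not None else "-"]
                if tok.gold_label is not None:
                    cols.append(tok.gold_label)
                if pred is not None:
                    cols.append(pred[i])
                fh.write(" ".join(cols) + "\n")
            fh.write("\n")
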