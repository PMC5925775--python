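"""Synthetic annotated corpora with controllable local-context structure.

The generator realizes the premise that an entity's type is signalled by cue
words in a small window around the mention: every generated entity of type t
is accompanied by a cue token drawn from t's cue lexicon, placed within
``cue_window`` tokens of the span (unless dropped with probability
``noise_rate``).  Entity surfaces are one- or two-token names with a
biomedical-looking shape (letter stems with digits and hyphens, e.g.
``brc-214``); all types share that morphology, so under the out-of-vocabulary
split the cue is the *only* signal distinguishing the types — the property
the locality-ablation tests exercise.

POS tags come from a small closed set correlated with token role (entity
tokens NN, cues NN, fillers a mix of DT/JJ/VB/IN/NN), standing in for a real
tagger.  Generation is a pure function of the spec's seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np

from .corpus import Chunk, Sentence, Token, ValidationError, encode_iob2

_FILLERS = (
    "the a of in to and with for on was were is are this that study analysis "
    "results level levels observed measured subjects samples after before "
    "during between increase decrease found show shown data using method "
    "group control total further also however present report case"
).split()

_FILLER_POS = ("DT", "JJ", "VB", "IN", "NN")

_DEFAULT_CUES = {
    "Gene": ("gene", "expression", "transcription", "promoter", "kinase", "protein"),
    "Disease": ("syndrome", "patients", "diagnosis", "disease", "carcinoma", "chronic"),
}


def _make_surface(rng: np.random.Generator) -> str:
    """One entity token: letter stem + hyphen + digits, e.g. ``brc-214``."""
    letters = "abcdefghijklmnopqrstuvwxyz"
    stem = "".join(rng.choice(list(letters), size=int(rng.integers(2, 5))))
    num = "".join(rng.choice(list("0123456789"), size=int(rng.integers(1, 4))))
    return f"{stem}-{num}"


def make_entity_lexicon(
    n_surfaces: int,
    rng: np.random.Generator,
    max_tokens: int = 2,
    suffix: str = "",
) -> tuple[tuple[str, ...], ...]:
    """Distinct multi-token entity surfaces (each a tuple of tokens).

    A non-empty ``suffix`` is appended to every token, giving the type a
    recognizable morphology (useful for character-feature experiments); by
    default all types share one neutral morphology.
    """
    out: list[tuple[str, ...]] = []
    seen: set[tuple[str, ...]] = set()
    while len(out) < n_surfaces:
        k = int(rng.integers(1, max_tokens + 1))
        surf = tuple(_make_surface(rng) + suffix for _ in range(k))
        if surf not in seen:
            seen.add(surf)
            out.append(surf)
    return tuple(out)


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic corpus.

    ``entity_lexicons`` maps each type to its (disjoint) surface inventory;
    ``cue_lexicons`` to its cue words.  ``entity_rate`` is the expected
    number of entities per sentence; ``cue_window`` the maximum distance in
    tokens between a cue and its entity span; ``noise_rate`` the probability
    that a cue is dropped.
    """

    n_sentences: int = 500
    sentence_length: tuple[int, int] = (15, 30)
    entity_lexicons: dict[str, tuple[tuple[str, ...], ...]] | None = None
    cue_lexicons: dict[str, tuple[str, ...]] | None = None
    cue_window: int = 2
    entity_rate: float = 1.5
    noise_rate: float = 0.0
    rng_seed: int = 0
    # Auto-generated lexicon size.  Kept large relative to the corpus so most
    # surfaces occur at most once or twice: biomedical entity vocabularies are
    # effectively open-ended, which is why surface memorization does not solve
    # real corpora and why character/context features are needed.
    n_surfaces_per_type: int = 400

    def materialize(self) -> "SyntheticSpec":
        """Fill in auto-generated lexicons (a deterministic function of the seed)."""
        spec = self
        rng = np.random.default_rng([self.rng_seed, 0xC0FFEE])
        if spec.cue_lexicons is None:
            spec = replace(spec, cue_lexicons=dict(_DEFAULT_CUES))
        if spec.entity_lexicons is None:
            lex: dict[str, tuple[tuple[str, ...], ...]] = {}
            taken: set[tuple[str, ...]] = set()
            for t in spec.cue_lexicons:
                surfaces = []
                while len(surfaces) < spec.n_surfaces_per_type:
                    for s in make_entity_lexicon(spec.n_surfaces_per_type, rng):
                        if s not in taken and len(surfaces) < spec.n_surfaces_per_type:
                            taken.add(s)
                            surfaces.append(s)
                lex[t] = tuple(surfaces)
            spec = replace(spec, entity_lexicons=lex)
        spec.validate()
        return spec

    def validate(self) -> None:
        if self.cue_window < 1:
            raise ValidationError("cue window must be >= 1")
        if self.entity_lexicons is None or self.cue_lexicons is None:
            return
        if set(self.entity_lexicons) != set(self.cue_lexicons):
            raise ValidationError("entity and cue lexicons must cover the same types")
        for t, lex in self.entity_lexicons.items():
            if not lex:
                raise ValidationError(f"empty entity lexicon for type {t!r}")
            if not self.cue_lexicons[t]:
                raise ValidationError(f"empty cue lexicon for type {t!r}")
        for a, b in itertools.combinations(self.entity_lexicons, 2):
            if set(self.entity_lexicons[a]) & set(self.entity_lexicons[b]):
                raise ValidationError(f"entity lexicons of {a!r} and {b!r} overlap")


def background_vocabulary(spec: SyntheticSpec) -> list[str]:
    """The corpus's non-entity vocabulary (fillers and cue words).

    This is the natural vocabulary for the frozen word-embedding table: like
    a table pre-trained on general text, it covers ordinary context words but
    not novel entity surfaces, which therefore map to UNK and must be
    recognized from character shape and context — the out-of-vocabulary
    situation the character embedding exists for.
    """
    spec = spec.materialize()
    cues = {c for lex in spec.cue_lexicons.values() for c in lex}
    return sorted(set(_FILLERS) | cues)


def _filler_token(rng: np.random.Generator) -> Token:
    word = str(rng.choice(_FILLERS))
    pos = str(rng.choice(_FILLER_POS))
    return Token(word, pos=pos)


def generate_corpus(
    spec: SyntheticSpec,
) -> tuple[list[Sentence], list[list[Chunk]]]:
    """Generate labeled sentences and their ground-truth chunks.

    With ``noise_rate == 0`` every entity has at least one cue of its type
    within ``cue_window`` tokens of the span.  Pure function of the seed.
    """
    spec = spec.materialize()
    rng = np.random.default_rng([spec.rng_seed, 1])
    types = sorted(spec.entity_lexicons)
    sentences: list[Sentence] = []
    all_chunks: list[list[Chunk]] = []

    for sid in range(spec.n_sentences):
        target_len = int(rng.integers(spec.sentence_length[0], spec.sentence_length[1] + 1))
        n_entities = min(int(rng.poisson(spec.entity_rate)), 3)
        tokens: list[Token] = []
        chunks: list[Chunk] = []
        for _ in range(n_entities):
            # leading fillers keep entities separated
            for _ in range(int(rng.integers(1, 4))):
                tokens.append(_filler_token(rng))
            t = types[int(rng.integers(len(types)))]
            surface = spec.entity_lexicons[t][int(rng.integers(len(spec.entity_lexicons[t])))]
            cue = str(rng.choice(spec.cue_lexicons[t]))
            keep_cue = rng.random() >= spec.noise_rate
            before = bool(rng.integers(2))
            gap = int(rng.integers(1, spec.cue_window + 1))  # distance cue <-> span edge
            if keep_cue and before:
                tokens.append(Token(cue, pos="NN"))
                for _ in range(gap - 1):
                    tokens.append(_filler_token(rng))
            start = len(tokens)
            for w in surface:
                tokens.append(Token(w, pos="NN"))
            chunks.append(Chunk(t, start, len(tokens)))
            if keep_cue and not before:
                for _ in range(gap - 1):
                    tokens.append(_filler_token(rng))
                tokens.append(Token(cue, pos="NN"))
        while len(tokens) < target_len:
            tokens.append(_filler_token(rng))
        labels = encode_iob2(len(tokens), chunks)
        tokens = [
            Token(tok.surface, pos=tok.pos, gold_label=lab)
            for tok, lab in zip(tokens, labels)
        ]
        sentences.append(Sentence(tokens, id=f"syn-{spec.rng_seed}-{sid}"))
        all_chunks.append(chunks)
    return sentences, all_chunks


def generate_char_oov_split(
    spec: SyntheticSpec,
    n_dev: int | None = None,
    n_test: int | None = None,
    fractions: tuple[float, float, float] = (0.7, 0.15, 0.15),
) -> tuple[list[Sentence], list[Sentence], list[Sentence]]:
    """Train/dev/test corpora whose entity surfaces are pairwise disjoint.

    Each type's surface inventory is split by ``fractions``; the three
    corpora are then generated independently (derived seeds), so a test
    entity surface never occurs in training and the model must rely on
    character shape and context cues.
    """
    spec = spec.materialize()
    rng = np.random.default_rng([spec.rng_seed, 2])
    splits: list[dict[str, tuple[tuple[str, ...], ...]]] = [{}, {}, {}]
    for t, lex in spec.entity_lexicons.items():
        n = len(lex)
        n_tr = int(round(fractions[0] * n))
        n_dv = int(round(fractions[1] * n))
        if n_tr < 1 or n_dv < 1 or n - n_tr - n_dv < 1:
            raise ValidationError(
                f"lexicon for type {t!r} has {n} surfaces; too few to split {fractions}"
            )
        perm = rng.permutation(n)
        splits[0][t] = tuple(lex[i] for i in perm[:n_tr])
        splits[1][t] = tuple(lex[i] for i in perm[n_tr : n_tr + n_dv])
        splits[2][t] = tuple(lex[i] for i in perm[n_tr + n_dv :])
    n_dev = n_dev if n_dev is not None else max(1, spec.n_sentences // 5)
    n_test = n_test if n_test is not None else max(1, spec.n_sentences // 5)
    out = []
    for part, (lex, n_sent) in enumerate(
        zip(splits, (spec.n_sentences, n_dev, n_test))
    ):
        sub = replace(
            spec,
            entity_lexicons=lex,
            n_sentences=n_sent,
            rng_seed=spec.rng_seed * 4 + part + 1,
        )
        out.append(generate_corpus(sub)[0])
    return tuple(out)  # type: ignore[return-value]
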