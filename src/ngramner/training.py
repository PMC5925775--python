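"""Initialization and the optimization loop.

Weights follow the published recipe: embedding tables are sampled uniformly
from +-sqrt(3/dim); convolution filters and fully connected layers use
Xavier-uniform initialization with zero biases.  Optimization is plain SGD
with momentum 0.9, initial learning rate 0.002 and a staircase decay of 0.95
every 50 000 optimizer steps (a step = one mini-batch update).  Training
keeps the checkpoint with the best development-set chunk F1 and stops early
when it has not improved for ``patience`` epochs.

The word-embedding table is frozen throughout; every other parameter group
(character and POS embeddings, all convolution filters, the scoring head and
the CRF transitions) receives gradient updates.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .corpus import LabelAlphabet, Sentence, ValidationError
from .embeddings import init_embedding  # re-exported: the embedding initializer
from .evaluation import evaluate_corpus
from .model import Model, loss_and_gradients, predict_corpus

__all__ = [
    "TrainConfig", "EpochRecord", "FitResult",
    "init_embedding", "init_layer", "xavier_uniform", "lr_at", "fit",
]


def xavier_uniform(
    fan_in: int, fan_out: int, shape: tuple[int, ...], rng: np.random.Generator
) -> np.ndarray:
    bound = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-bound, bound, size=shape)


def init_layer(
    shape: tuple[int, int], rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Xavier-uniform weight matrix (fan_in, fan_out) and an exactly-zero bias."""
    fan_in, fan_out = shape
    return xavier_uniform(fan_in, fan_out, shape, rng), np.zeros(fan_out)


@dataclass
class TrainConfig:
    initial_lr: float = 0.002
    decay: float = 0.95
    decay_steps: int = 50_000
    momentum: float = 0.9
    max_epochs: int = 100
    batch_size: int = 16
    patience: int = 10
    clip_norm: float = 5.0
    rng_seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.decay <= 1.0:
            raise ValueError("decay must be in (0, 1]")
        if self.initial_lr <= 0.0:
            raise ValueError("learning rate must be positive")


def lr_at(step: int, cfg: TrainConfig) -> float:
    """Staircase schedule: lr0 * decay ** floor(step / decay_steps)."""
    if step < 0:
        raise ValueError("step must be >= 0")
    return cfg.initial_lr * cfg.decay ** (step // cfg.decay_steps)


@dataclass
class EpochRecord:
    epoch: int
    mean_nll: float
    dev_precision: float
    dev_recall: float
    dev_f1: float
    lr: float

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class FitResult:
    model: Model  # parameters of the best dev-F1 epoch
    log: list[EpochRecord]
    best_epoch: int
    best_dev_f1: float


def _check_corpora(
    train: list[Sentence], dev: list[Sentence], labels: LabelAlphabet
) -> None:
    if not train or not dev:
        raise ValidationError("training and development corpora must be non-empty")
    missing = sorted(
        {lab for s in dev for lab in s.gold_labels if lab not in labels}
    )
    if missing:
        raise ValidationError(
            f"development labels absent from the training alphabet: {missing}"
        )


def _global_norm(grads: dict[str, np.ndarray]) -> float:
    return float(np.sqrt(sum(float((g * g).sum()) for g in grads.values())))


def fit(
    train: list[Sentence],
    dev: list[Sentence],
    model: Model,
    cfg: TrainConfig | None = None,
) -> FitResult:
    """Train the model, logging one record per epoch and returning the
    parameters of the epoch with the best development chunk F1.

    All randomness (shuffling, dropout) is driven by ``cfg.rng_seed``; two
    runs with the same seed produce identical logs.  Gradients are
    accumulated over ``batch_size`` sentences per update and clipped at
    global norm ``clip_norm``.
    """
    cfg = cfg if cfg is not None else TrainConfig()
    _check_corpora(train, dev, model.labels)
    rng = np.random.default_rng(cfg.rng_seed)

    params = model.trainable_arrays()
    word_before = model.word_table.matrix.copy()
    velocity = {k: np.zeros_like(v) for k, v in params.items()}
    step = 0
    log: list[EpochRecord] = []
    best_f1, best_epoch, best_state = -1.0, -1, None
    stale = 0

    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(len(train))
        total_nll = 0.0
        for lo in range(0, len(order), cfg.batch_size):
            batch = [train[i] for i in order[lo : lo + cfg.batch_size]]
            acc: dict[str, np.ndarray] = {k: np.zeros_like(v) for k, v in params.items()}
            for sent in batch:
                nll, grads = loss_and_gradients(model, sent, rng=rng, training=True)
                total_nll += nll
                for k, g in grads.items():
                    acc[k] += g
            for k in acc:
                acc[k] /= len(batch)
            norm = _global_norm(acc)
            if cfg.clip_norm > 0 and norm > cfg.clip_norm:
                scale = cfg.clip_norm / norm
                for k in acc:
                    acc[k] *= scale
            lr = lr_at(step, cfg)
            for k, p in params.items():
                velocity[k] = cfg.momentum * velocity[k] - lr * acc[k]
                p += velocity[k]
            step += 1

        predictions = predict_corpus(model, dev)
        res = evaluate_corpus(dev, predictions)
        rec = EpochRecord(
            epoch=epoch,
            mean_nll=total_nll / len(train),
            dev_precision=res.overall.precision,
            dev_recall=res.overall.recall,
            dev_f1=res.overall.f1,
            lr=lr_at(step, cfg),
        )
        log.append(rec)

        if rec.dev_f1 > best_f1:
            best_f1, best_epoch = rec.dev_f1, epoch
            best_state = {k: v.copy() for k, v in params.items()}
            stale = 0
        else:
            stale += 1
            if stale >= cfg.patience:
                break

    assert best_state is not None
    for k, p in params.items():
        p[...] = best_state[k]
    if not np.array_equal(word_before, model.word_table.matrix):
        raise AssertionError("frozen word-embedding table was modified during training")
    return FitResult(model=model, log=log, best_epoch=best_epoch, best_dev_f1=best_f1)
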