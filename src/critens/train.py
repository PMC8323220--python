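"""Reproducible single-model training with the combined objective.

Each epoch shuffles the training split with a seeded generator, iterates
mini-batches, and minimizes FocalLoss + mu * L_metric with Adam.  The
metric loss is computed within each mini-batch over the classes present in
that batch (batch-scoped metric learning; the full-training-set pairwise
sum would be quadratic in corpus size).  Weight decay is applied to the
convolution and classifier weights; gradients are clipped at global norm
5.0 to keep the hinge term from dominating early.  The returned checkpoint
is the epoch with the best validation macro F1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .corpus import (
    CategorySchema,
    LabeledText,
    split_records,
    subsample_training_set,
)
from .encoder import EncoderConfig, Vocabulary, build_vocabulary, init_embedding, tokenize_batch
from .evaluate import compute_metrics, confusion_counts
from .losses import LossConfig, focal_loss_grad_logits, metric_loss_grad
from .model import ModelConfig, TextCNN

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "TrainedModel",
    "train_single_model",
    "subsample_training_set",
    "run_data_volume_experiment",
]

logger = logging.getLogger(__name__)

GRAD_CLIP_NORM = 5.0


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters.

    The default learning rate 3e-3 suits randomly initialized character
    embeddings trained from scratch; fine-tuning externally pre-trained
    encoders conventionally uses 2e-5.
    """

    learning_rate: float = 3e-3
    batch_size: int = 128
    epochs: int = 12
    seed: int = 0
    weight_decay: float = 1e-4

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.batch_size < 1 or self.epochs < 1:
            raise ValueError("learning_rate, batch_size and epochs must be positive")
        if self.weight_decay < 0:
            raise ValueError("weight_decay must be non-negative")


@dataclass
class TrainHistory:
    """Per-epoch training diagnostics."""

    total_loss: list[float] = field(default_factory=list)
    focal_loss: list[float] = field(default_factory=list)
    metric_loss: list[float] = field(default_factory=list)
    valid_macro_f1: list[float] = field(default_factory=list)
    best_epoch: int = -1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": np.arange(1, len(self.total_loss) + 1),
                "total_loss": self.total_loss,
                "focal_loss": self.focal_loss,
                "metric_loss": self.metric_loss,
                "valid_macro_f1": self.valid_macro_f1,
            }
        )


@dataclass
class TrainedModel:
    """A trained single model bundled with everything needed for inference."""

    model: TextCNN
    vocab: Vocabulary
    encoder_config: EncoderConfig
    schema: CategorySchema
    history: TrainHistory

    def predict_proba(self, texts: list[str]) -> np.ndarray:
        ids, mask = tokenize_batch(texts, self.vocab, self.encoder_config.max_length)
        return self.model.predict_proba(ids, mask)

    def features(self, texts: list[str]) -> np.ndarray:
        ids, mask = tokenize_batch(texts, self.vocab, self.encoder_config.max_length)
        return self.model.features(ids, mask)

    def predict(self, texts: list[str]) -> np.ndarray:
        return self.predict_proba(texts).argmax(axis=1)


class Adam:
    """Adaptive-moment optimizer over a parameter dict."""

    def __init__(self, params: dict[str, np.ndarray], lr: float, weight_decay: float):
        self.lr = lr
        self.weight_decay = weight_decay
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        # decay acts on weight matrices, not biases or the embedding table
        self.decayed = {k for k in params if k.endswith("_W")}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, g in grads.items():
            if k in self.decayed and self.weight_decay:
                g = g + self.weight_decay * params[k]
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            mhat = self.m[k] / (1 - self.beta1**self.t)
            vhat = self.v[k] / (1 - self.beta2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _clip_gradients(grads: dict[str, np.ndarray], max_norm: float) -> None:
    total = np.sqrt(sum(float((g * g).sum()) for g in grads.values()))
    if total > max_norm:
        scale = max_norm / total
        for g in grads.values():
            g *= scale


def _macro_f1(model: TextCNN, ids: np.ndarray, mask: np.ndarray, y: np.ndarray, n: int) -> float:
    pred = model.predict_proba(ids, mask).argmax(axis=1)
    return compute_metrics(confusion_counts(y, pred, n)).macro_f1


def train_single_model(
    records: list[LabeledText],
    schema: CategorySchema,
    encoder_config: EncoderConfig,
    model_config: ModelConfig | None = None,
    loss_config: LossConfig | None = None,
    train_config: TrainConfig | None = None,
) -> TrainedModel:
    """Train one character-level model with the combined objective.

    Deterministic for fixed (records, configs, seed) on a fixed platform.
    Returns the checkpoint from the epoch with the best validation macro F1
    (earliest epoch wins ties).
    """
    loss_config = loss_config or LossConfig()
    train_config = train_config or TrainConfig()
    train = split_records(records, "train")
    valid = split_records(records, "valid")
    if not train or not valid:
        raise ValueError("corpus needs non-empty train and valid splits")

    vocab = build_vocabulary(r.text for r in train)
    model_config = model_config or ModelConfig(n_classes=schema.n)
    if model_config.n_classes != schema.n:
        raise ValueError("model n_classes must match the corpus schema")
    embedding = init_embedding(vocab, encoder_config)
    model = TextCNN(model_config, embedding, seed=encoder_config.seed)

    ids_tr, mask_tr = tokenize_batch(
        [r.text for r in train], vocab, encoder_config.max_length
    )
    y_tr = np.array([r.label for r in train])
    ids_va, mask_va = tokenize_batch(
        [r.text for r in valid], vocab, encoder_config.max_length
    )
    y_va = np.array([r.label for r in valid])

    optimizer = Adam(model.params, train_config.learning_rate, train_config.weight_decay)
    rng = np.random.default_rng(train_config.seed)
    history = TrainHistory()
    best_f1, best_state, best_epoch = -1.0, model.state_dict(), 0

    n_train = len(train)
    for epoch in range(1, train_config.epochs + 1):
        order = rng.permutation(n_train)
        ep_total = ep_focal = ep_metric = 0.0
        n_batches = 0
        for start in range(0, n_train, train_config.batch_size):
            batch = order[start : start + train_config.batch_size]
            cache = model.forward(ids_tr[batch], mask_tr[batch])
            y_b = y_tr[batch]
            f_loss, dlogits = focal_loss_grad_logits(
                cache["logits"], y_b, loss_config.gamma
            )
            m_loss, dr_metric = metric_loss_grad(cache["r"], y_b, loss_config)
            total = f_loss + loss_config.mu * m_loss
            if not np.isfinite(total):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}: focal={f_loss}, metric={m_loss}"
                )
            grads = model.backward(
                cache,
                dlogits,
                dr_extra=loss_config.mu * dr_metric if loss_config.mu else None,
            )
            _clip_gradients(grads, GRAD_CLIP_NORM)
            optimizer.step(model.params, grads)
            ep_total += total
            ep_focal += f_loss
            ep_metric += m_loss
            n_batches += 1
        f1 = _macro_f1(model, ids_va, mask_va, y_va, schema.n)
        history.total_loss.append(ep_total / n_batches)
        history.focal_loss.append(ep_focal / n_batches)
        history.metric_loss.append(ep_metric / n_batches)
        history.valid_macro_f1.append(f1)
        logger.info(
            '{"epoch": %d, "loss": %.6f, "focal": %.6f, "metric": %.6f, "valid_macro_f1": %.4f}',
            epoch,
            ep_total / n_batches,
            ep_focal / n_batches,
            ep_metric / n_batches,
            f1,
        )
        if f1 > best_f1:
            best_f1, best_state, best_epoch = f1, model.state_dict(), epoch

    model.load_state_dict(best_state)
    history.best_epoch = best_epoch
    return TrainedModel(
        model=model,
        vocab=vocab,
        encoder_config=encoder_config,
        schema=schema,
        history=history,
    )


def run_data_volume_experiment(
    records: list[LabeledText],
    schema: CategorySchema,
    fractions: list[float],
    encoder_configs: list[EncoderConfig],
    model_config: ModelConfig | None = None,
    loss_config: LossConfig | None = None,
    train_config: TrainConfig | None = None,
    subsample_seed: int = 0,
) -> pd.DataFrame:
    """Train one model per (fraction, encoder) on a subsampled training split.

    Returns a tidy table with columns encoder_id, fraction, test_macro_f1,
    valid_macro_f1.  Fractions must include 1.0 so the full-data reference
    point is present.
    """
    if not fractions:
        raise ValueError("fractions must be non-empty")
    if 1.0 not in fractions:
        raise ValueError("fractions must include 1.0")
    test = split_records(records, "test")
    y_test = np.array([r.label for r in test])
    rows = []
    for enc in encoder_configs:
        for frac in fractions:
            reduced = subsample_training_set(records, frac, seed=subsample_seed)
            trained = train_single_model(
                reduced, schema, enc, model_config, loss_config, train_config
            )
            pred = trained.predict([r.text for r in test])
            report = compute_metrics(confusion_counts(y_test, pred, schema.n))
            rows.append(
                {
                    "encoder_id": enc.encoder_id,
                    "fraction": frac,
                    "test_macro_f1": report.macro_f1,
                    "valid_macro_f1": max(trained.history.valid_macro_f1),
                }
            )
    return pd.DataFrame(rows)
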