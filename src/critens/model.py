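"""Single-model architecture: embeddings -> multi-width convolution with
masked max-pooling -> feature representation r -> linear layer -> softmax.

The sequence-modeling layer runs one 1-D convolution per kernel width
(3, 4 and 5 by default) over the character embeddings, applies a rectifier,
and max-pools each filter over the valid windows — those overlapping at
least one real (non-PAD) token.  The pooled outputs are concatenated into
the feature representation r of dimension (#widths x filters per width),
which is both the classifier input and the representation fed to the
metric loss.  Each sequence is right-padded by w-1 zero (PAD) positions
inside the convolution and windows lying entirely over padding are
excluded from the max, so appending PAD positions never changes r.

Implemented in NumPy with hand-derived gradients; `backward` returns
parameter gradients given upstream gradients on the logits and on r, and
is validated against numerical differentiation in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .encoder import PAD_ID
from .losses import softmax


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters of one single model."""

    kernel_widths: tuple[int, ...] = (3, 4, 5)
    filters_per_width: int = 16
    n_classes: int = 2
    encoder_id: str = "char-emb-0"

    def __post_init__(self) -> None:
        if any(w < 1 for w in self.kernel_widths):
            raise ValueError("kernel widths must be positive")
        if self.filters_per_width < 1:
            raise ValueError("filters_per_width must be positive")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")

    @property
    def feature_dim(self) -> int:
        """Dimension d of the feature representation r."""
        return len(self.kernel_widths) * self.filters_per_width


class TextCNN:
    """Character-level convolutional classifier over a trainable embedding.

    Parameters live in ``self.params``: the embedding table ``emb``
    (PAD row frozen at zero), per-width convolution kernels ``conv{w}_W``
    of shape (w * embedding_dim, filters) with biases ``conv{w}_b``, and
    the classifier ``fc_W`` (n_classes x d), ``fc_b``.
    """

    def __init__(
        self,
        config: ModelConfig,
        embedding: np.ndarray,
        seed: int = 0,
    ) -> None:
        self.config = config
        self.embedding_dim = embedding.shape[1]
        if min(config.kernel_widths) > 0 and embedding.shape[0] < 2:
            raise ValueError("embedding table must include PAD and UNK rows")
        rng = np.random.default_rng(seed)
        d = config.feature_dim
        self.params: dict[str, np.ndarray] = {"emb": embedding.astype(float).copy()}
        self.params["emb"][PAD_ID] = 0.0
        for w in config.kernel_widths:
            fan_in = w * self.embedding_dim
            self.params[f"conv{w}_W"] = rng.normal(
                0.0, np.sqrt(2.0 / fan_in), size=(fan_in, config.filters_per_width)
            )
            self.params[f"conv{w}_b"] = np.zeros(config.filters_per_width)
        self.params["fc_W"] = rng.normal(0.0, np.sqrt(1.0 / d), size=(config.n_classes, d))
        self.params["fc_b"] = np.zeros(config.n_classes)

    # -- forward -----------------------------------------------------------

    def forward(self, ids: np.ndarray, mask: np.ndarray) -> dict[str, Any]:
        """Full forward pass on a batch; returns a cache for backward.

        ids, mask: integer arrays of shape (B, L).  Raises if any sequence
        is all-PAD (no valid pooling window exists).
        """
        ids = np.atleast_2d(ids)
        mask = np.atleast_2d(mask)
        if not mask.any(axis=1).all():
            raise ValueError("all-PAD sequence: no valid convolution window")
        if ids.shape[1] < max(self.config.kernel_widths):
            raise ValueError("sequence length below largest kernel width")
        emb = self.params["emb"]
        x = emb[ids]  # (B, L, D)
        cache: dict[str, Any] = {"ids": ids, "mask": mask, "x": x, "per_width": {}}
        pooled = []
        for w in self.config.kernel_widths:
            cols, valid = _im2col(x, mask, w)
            z = cols @ self.params[f"conv{w}_W"] + self.params[f"conv{w}_b"]
            a = np.maximum(z, 0.0)
            # invalid windows must not win the max
            a_masked = np.where(valid[:, :, None], a, -np.inf)
            arg = a_masked.argmax(axis=1)  # (B, F)
            pool = np.take_along_axis(a_masked, arg[:, None, :], axis=1)[:, 0, :]
            pool = np.maximum(pool, 0.0)  # -inf cannot occur; ReLU floor is 0
            cache["per_width"][w] = {"cols": cols, "valid": valid, "z": z, "arg": arg}
            pooled.append(pool)
        r = np.concatenate(pooled, axis=1)  # (B, d)
        logits = r @ self.params["fc_W"].T + self.params["fc_b"]
        cache["r"] = r
        cache["logits"] = logits
        cache["probs"] = softmax(logits)
        return cache

    def features(self, ids: np.ndarray, mask: np.ndarray) -> np.ndarray:
        """Feature representations r for a batch, shape (B, d)."""
        return self.forward(ids, mask)["r"]

    def predict_proba(self, ids: np.ndarray, mask: np.ndarray) -> np.ndarray:
        """Softmax class probabilities for a batch, shape (B, n_classes)."""
        cache = self.forward(ids, mask)
        if not np.isfinite(cache["r"]).all():
            raise ValueError("non-finite feature representation")
        return cache["probs"]

    # -- backward ----------------------------------------------------------

    def backward(
        self,
        cache: dict[str, Any],
        dlogits: np.ndarray,
        dr_extra: np.ndarray | None = None,
    ) -> dict[str, np.ndarray]:
        """Parameter gradients given upstream gradients.

        dlogits is dLoss/dlogits (B x n); dr_extra is an optional additional
        dLoss/dr (B x d) coming from the metric loss on the representations.
        The PAD embedding row's gradient is zeroed (frozen parameter).
        """
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        r = cache["r"]
        grads["fc_W"] = dlogits.T @ r
        grads["fc_b"] = dlogits.sum(axis=0)
        dr = dlogits @ self.params["fc_W"]
        if dr_extra is not None:
            dr = dr + dr_extra

        ids, mask, x = cache["ids"], cache["mask"], cache["x"]
        batch, length, dim = x.shape
        dx = np.zeros_like(x)
        offset = 0
        nf = self.config.filters_per_width
        for w in self.config.kernel_widths:
            cw = cache["per_width"][w]
            dpool = dr[:, offset : offset + nf]  # (B, F)
            offset += nf
            # route through max-pool: only the argmax window receives gradient
            da = np.zeros_like(cw["z"])  # (B, T, F)
            np.put_along_axis(da, cw["arg"][:, None, :], dpool[:, None, :], axis=1)
            # ReLU
            dz = da * (cw["z"] > 0.0)
            grads[f"conv{w}_W"] = np.einsum("btk,btf->kf", cw["cols"], dz)
            grads[f"conv{w}_b"] = dz.sum(axis=(0, 1))
            dcols = dz @ self.params[f"conv{w}_W"].T  # (B, L, w*D)
            dcols = dcols.reshape(batch, length, w, dim)
            dxp = np.zeros((batch, length + w - 1, dim))
            for u in range(w):
                dxp[:, u : u + length, :] += dcols[:, :, u, :]
            dx += dxp[:, :length, :]  # the padded tail is not a parameter
        # scatter-add into the embedding table
        np.add.at(grads["emb"], ids.ravel(), dx.reshape(-1, dim))
        grads["emb"][PAD_ID] = 0.0
        return grads

    # -- persistence -------------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = state[k].copy()


def _im2col(
    x: np.ndarray, mask: np.ndarray, w: int
) -> tuple[np.ndarray, np.ndarray]:
    """Unfold (B, L, D) into the w-wide sliding windows starting at 0..L-1.

    The sequence is right-padded with w-1 zero (PAD-embedding) positions so
    that every window overlapping a real token exists regardless of L; this
    is what makes the feature representation invariant to appending PAD.
    A window is valid when it overlaps at least one real token; texts are
    left-aligned (mask is a prefix of ones), so window t is valid iff
    position t is real.
    """
    batch, length, dim = x.shape
    xp = np.concatenate([x, np.zeros((batch, w - 1, dim))], axis=1)
    windows = np.lib.stride_tricks.sliding_window_view(xp, w, axis=1)
    # sliding_window_view yields (B, L, D, w); reorder to (B, L, w*D)
    cols = windows.transpose(0, 1, 3, 2).reshape(batch, length, w * dim)
    valid = mask.astype(bool)
    return np.ascontiguousarray(cols), valid


# ---------------------------------------------------------------------------
# Spec-level operations on single sequences
# ---------------------------------------------------------------------------


def sequence_encode(
    embedded: np.ndarray,
    mask: np.ndarray,
    conv_weights: dict[int, tuple[np.ndarray, np.ndarray]],
) -> np.ndarray:
    """Feature representation of one embedded sequence (L x D).

    conv_weights maps kernel width w to (W, b) with W of shape (w*D, F).
    For each width the rectified convolution output is max-pooled over the
    windows overlapping at least one real token, and the pooled vectors are
    concatenated in increasing width order.
    """
    embedded = np.asarray(embedded, dtype=float)
    mask = np.asarray(mask)
    if not mask.any():
        raise ValueError("all-PAD sequence: no valid convolution window")
    pooled = []
    for w in sorted(conv_weights):
        weight, bias = conv_weights[w]
        cols, valid = _im2col(embedded[None], mask[None], w)
        z = np.maximum(cols[0] @ weight + bias, 0.0)
        z = np.where(valid[0][:, None], z, -np.inf)
        pooled.append(np.maximum(z.max(axis=0), 0.0))
    return np.concatenate(pooled)


def classify(
    r: np.ndarray, weight: np.ndarray, bias: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Linear scores x = W r + b and probabilities p = softmax(x)."""
    r = np.asarray(r, dtype=float)
    if not np.isfinite(r).all():
        raise ValueError("non-finite feature representation")
    logits = weight @ r + bias
    return logits, softmax(logits)[0]
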