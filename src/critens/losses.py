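"""The combined training objective: focal loss plus pairwise metric loss.

Feature distance between two representations is the dimension-normalized
squared Euclidean distance D(r_i, r_j) = (1/d) ||r_i - r_j||^2.  On a batch
grouped into per-class sets S_k the metric loss is

    L_metric = sum_k { L_intra(k) + lambda * sum_{i != k} L_inter(k, i) }

with the intra-class term the mean of D over all unordered same-class pairs
and the inter-class term the mean hinge max(0, m - D) over all cross-class
pairs.  The inner sum over i != k visits each unordered class pair twice,
once per orientation; it is computed exactly as written (no halving), and
lambda absorbs the constant factor.

The classification term is the focal loss -(1 - p_t)^gamma * log(p_t) on
the true-class probability p_t, averaged over the batch; at gamma = 0 it
reduces to cross-entropy on the true class.  The combined objective is
L = FocalLoss + mu * L_metric.

Conventions: natural logarithm throughout; probabilities clamped to
[1e-12, 1] inside logarithms; classes with fewer than two members
contribute zero intra-class loss and empty classes zero inter-class loss.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_EPS = 1e-12


@dataclass(frozen=True)
class LossConfig:
    """Hyperparameters of the combined objective.

    gamma: focal modulation exponent (0 recovers cross-entropy).
    lambda_: weight of the inter-class term inside the metric loss.
    mu: weight of the metric loss inside the combined objective.
    margin: desired minimum inter-class feature distance m; cross pairs
        farther apart than m incur zero inter-class loss.
    """

    gamma: float = 2.0
    lambda_: float = 0.1
    mu: float = 1.0
    margin: float = 0.1

    def __post_init__(self) -> None:
        for name in ("gamma", "lambda_", "mu"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and non-negative")
        if not np.isfinite(self.margin) or self.margin <= 0:
            raise ValueError("margin must be finite and positive")


# ---------------------------------------------------------------------------
# Feature distance and metric-loss components
# ---------------------------------------------------------------------------


def feature_distance(r_i: np.ndarray, r_j: np.ndarray) -> float:
    """Dimension-normalized squared Euclidean distance between two vectors."""
    r_i = np.asarray(r_i, dtype=float)
    r_j = np.asarray(r_j, dtype=float)
    if r_i.shape != r_j.shape or r_i.ndim != 1:
        raise ValueError("representations must be 1-D vectors of equal dimension")
    d = r_i.shape[0]
    diff = r_i - r_j
    return float(diff @ diff) / d


def _pairwise_distances(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Matrix of D(a_i, b_j) for rows of a (n x d) and b (m x d)."""
    d = a.shape[1]
    sq = (
        (a * a).sum(axis=1)[:, None]
        + (b * b).sum(axis=1)[None, :]
        - 2.0 * a @ b.T
    )
    return np.maximum(sq, 0.0) / d


def intra_class_loss(members: np.ndarray) -> float:
    """Mean feature distance over all unordered same-class pairs.

    Fewer than two members give zero (the pair mean is undefined there).
    """
    members = np.atleast_2d(np.asarray(members, dtype=float))
    s = members.shape[0]
    if s < 2:
        return 0.0
    dmat = _pairwise_distances(members, members)
    total = dmat[np.triu_indices(s, k=1)].sum()
    return float(2.0 * total / (s * s - s))


def inter_class_loss(
    members_p: np.ndarray, members_q: np.ndarray, margin: float
) -> float:
    """Mean hinge max(0, m - D) over all cross-class pairs; 0 if a set is empty."""
    members_p = np.atleast_2d(np.asarray(members_p, dtype=float))
    members_q = np.atleast_2d(np.asarray(members_q, dtype=float))
    if members_p.size == 0 or members_q.size == 0:
        return 0.0
    dmat = _pairwise_distances(members_p, members_q)
    hinge = np.maximum(0.0, margin - dmat)
    return float(hinge.mean())


def metric_loss(
    representations: np.ndarray, labels: np.ndarray, config: LossConfig
) -> float:
    """Total metric loss over the classes present in a batch."""
    value, _ = metric_loss_grad(representations, labels, config)
    return value


def metric_loss_grad(
    representations: np.ndarray, labels: np.ndarray, config: LossConfig
) -> tuple[float, np.ndarray]:
    """Metric loss and its gradient with respect to the representations.

    The gradient of D(r_i, r_j) in r_i is (2/d)(r_i - r_j); intra pairs pull
    together, cross pairs inside the margin push apart.
    """
    reps = np.asarray(representations, dtype=float)
    labels = np.asarray(labels)
    if reps.ndim != 2 or reps.shape[0] != labels.shape[0]:
        raise ValueError("representations must be (batch, d) aligned with labels")
    d = reps.shape[1]
    grad = np.zeros_like(reps)
    classes = np.unique(labels)
    idx_of = {int(k): np.flatnonzero(labels == k) for k in classes}

    total = 0.0
    for k in classes:
        idx_k = idx_of[int(k)]
        s = len(idx_k)
        if s >= 2:
            members = reps[idx_k]
            dmat = _pairwise_distances(members, members)
            coeff = 2.0 / (s * s - s)
            total += coeff * dmat[np.triu_indices(s, k=1)].sum()
            # grad of sum_{i<j} D: each row i gets (2/d) sum_{j != i} (r_i - r_j)
            diff = members[:, None, :] - members[None, :, :]
            grad[idx_k] += coeff * (2.0 / d) * diff.sum(axis=1)
        for q in classes:
            if q == k:
                continue
            idx_q = idx_of[int(q)]
            members_p, members_q = reps[idx_k], reps[idx_q]
            dmat = _pairwise_distances(members_p, members_q)
            active = dmat < config.margin
            coeff = config.lambda_ / (len(idx_k) * len(idx_q))
            total += coeff * np.maximum(0.0, config.margin - dmat).sum()
            if active.any():
                diff = members_p[:, None, :] - members_q[None, :, :]
                w = active.astype(float)[:, :, None]
                g = coeff * (2.0 / d) * (w * diff)
                grad[idx_k] -= g.sum(axis=1)
                grad[idx_q] += g.sum(axis=0)
    return float(total), grad


# ---------------------------------------------------------------------------
# Classification losses
# ---------------------------------------------------------------------------


def _true_class_probs(p: np.ndarray, y: np.ndarray) -> np.ndarray:
    p = np.atleast_2d(np.asarray(p, dtype=float))
    y = np.atleast_1d(np.asarray(y))
    if np.any(np.abs(p.sum(axis=1) - 1.0) > 1e-6) or np.any(p < -1e-9):
        raise ValueError("rows must be valid probability vectors")
    return np.clip(p[np.arange(len(y)), y], _EPS, 1.0)


def cross_entropy_loss(p: np.ndarray, y: np.ndarray | int) -> float:
    """Mean negative log-probability of the true class (one-hot targets)."""
    p_t = _true_class_probs(p, np.atleast_1d(np.asarray(y)))
    return float(np.mean(-np.log(p_t)))


def focal_loss(p: np.ndarray, y: np.ndarray | int, gamma: float = 2.0) -> float:
    """Mean focal loss -(1 - p_t)^gamma * log(p_t) over the batch."""
    if gamma < 0:
        raise ValueError("gamma must be non-negative")
    p_t = _true_class_probs(p, np.atleast_1d(np.asarray(y)))
    return float(np.mean(-((1.0 - p_t) ** gamma) * np.log(p_t)))


def focal_loss_grad_logits(
    logits: np.ndarray, y: np.ndarray, gamma: float
) -> tuple[float, np.ndarray]:
    """Batch-mean focal loss and its gradient with respect to the logits.

    With p = softmax(x) and p_t the true-class entry,
    dFL/dp_t = gamma (1-p_t)^(gamma-1) log p_t - (1-p_t)^gamma / p_t and
    dp_t/dx_j = p_t (delta_{jt} - p_j); gamma = 0 recovers the familiar
    cross-entropy gradient p - onehot(y).
    """
    logits = np.atleast_2d(np.asarray(logits, dtype=float))
    y = np.atleast_1d(np.asarray(y))
    b = logits.shape[0]
    p = softmax(logits)
    p_t = np.clip(p[np.arange(b), y], _EPS, 1.0)
    one_minus = 1.0 - p_t
    loss = float(np.mean(-(one_minus**gamma) * np.log(p_t)))
    if gamma == 0.0:
        dloss_dpt = -1.0 / p_t
    else:
        dloss_dpt = gamma * (one_minus ** (gamma - 1.0)) * np.log(p_t) - (
            one_minus**gamma
        ) / p_t
    # dp_t/dx_j = p_t (delta_jt - p_j)
    grad = -p * (dloss_dpt * p_t)[:, None]
    grad[np.arange(b), y] += dloss_dpt * p_t
    return loss, grad / b


def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax, shift-invariant and overflow-safe."""
    logits = np.atleast_2d(np.asarray(logits, dtype=float))
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def combined_loss(
    p: np.ndarray,
    y: np.ndarray,
    representations: np.ndarray,
    labels: np.ndarray,
    config: LossConfig,
) -> float:
    """L = FocalLoss + mu * L_metric on one batch."""
    return focal_loss(p, y, config.gamma) + config.mu * metric_loss(
        representations, labels, config
    )
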