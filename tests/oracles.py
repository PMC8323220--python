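"""Independent brute-force reference implementations used as test oracles.

Everything here is written as plain Python loops over the printed formulas,
deliberately sharing no code with the package implementation.
"""

from __future__ import annotations

import math

import numpy as np


def distance_oracle(r_i, r_j) -> float:
    d = len(r_i)
    return sum((a - b) ** 2 for a, b in zip(r_i, r_j)) / d


def intra_oracle(members) -> float:
    s = len(members)
    if s < 2:
        return 0.0
    total = 0.0
    for i in range(s):
        for j in range(i + 1, s):
            total += distance_oracle(members[i], members[j])
    return 2.0 / (s * s - s) * total


def inter_oracle(members_p, members_q, m) -> float:
    if not len(members_p) or not len(members_q):
        return 0.0
    total = 0.0
    for a in members_p:
        for b in members_q:
            total += max(0.0, m - distance_oracle(a, b))
    return total / (len(members_p) * len(members_q))


def metric_oracle(reps, labels, lam, m) -> float:
    classes = sorted(set(int(l) for l in labels))
    groups = {k: [r for r, l in zip(reps, labels) if l == k] for k in classes}
    total = 0.0
    for k in classes:
        total += intra_oracle(groups[k])
        for i in classes:
            if i != k:
                total += lam * inter_oracle(groups[k], groups[i], m)
    return total


def ce_oracle(p_row, y) -> float:
    return -math.log(max(p_row[y], 1e-12))


def focal_oracle(p_row, y, gamma) -> float:
    p_t = max(p_row[y], 1e-12)
    return -((1.0 - p_t) ** gamma) * math.log(p_t)


def paired_t_oracle(a, b) -> tuple[float, float]:
    """Textbook paired t: t = mean(d) / (sd(d)/sqrt(n)), two-sided p."""
    from scipy.stats import t as t_dist

    d = [x - y for x, y in zip(a, b)]
    n = len(d)
    mean = sum(d) / n
    var = sum((x - mean) ** 2 for x in d) / (n - 1)
    t_stat = mean / math.sqrt(var / n)
    p = 2.0 * t_dist.sf(abs(t_stat), df=n - 1)
    return t_stat, p


def conv_pool_oracle(rows, mask, weights_by_width, biases_by_width):
    """Brute-force multi-width conv + ReLU + masked max-pool on one sequence.

    rows: L x D, weights_by_width[w]: (w*D, F).  The sequence is implicitly
    right-padded with zero rows so every window overlapping a real position
    exists; a window is valid when it overlaps at least one masked-in
    position.
    """
    L = len(rows)
    D = len(rows[0])
    pooled = []
    for w in sorted(weights_by_width):
        W = weights_by_width[w]
        b = biases_by_width[w]
        padded = [np.asarray(r, dtype=float) for r in rows] + [
            np.zeros(D) for _ in range(w - 1)
        ]
        pmask = list(mask) + [0] * (w - 1)
        best = None
        for t in range(L):
            if not any(pmask[t : t + w]):
                continue
            window = np.concatenate([padded[t + u] for u in range(w)])
            z = np.maximum(window @ W + b, 0.0)
            best = z if best is None else np.maximum(best, z)
        pooled.append(best)
    return np.concatenate(pooled)
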