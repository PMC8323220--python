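"""Shared fixtures and a memoized training cache.

The directional experiments (metric-learning effect, focal-vs-CE, ensemble
gain, data-volume trend) all train models on the same synthetic benchmark
conditions; `trained_run` memoizes each distinct (corpus seed, run seed,
objective variant, training fraction) so runs shared between experiments
are trained once per session.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from critens import (
    CategorySchema,
    EncoderConfig,
    LabeledText,
    LossConfig,
    SyntheticSpec,
    TrainConfig,
    compute_metrics,
    confusion_counts,
    generate_synthetic_corpus,
    split_records,
    subsample_training_set,
    train_single_model,
)
from critens.api import mean_pairwise_distances

# Benchmark study conditions: 8 classes, 2000 samples, Zipf exponent 1.5,
# 30% shared-noise tokens.  These are the SyntheticSpec defaults.
BENCHMARK = SyntheticSpec()


@lru_cache(maxsize=None)
def benchmark_corpus(corpus_seed: int):
    spec = SyntheticSpec(seed=corpus_seed)
    return generate_synthetic_corpus(spec)


@dataclass(frozen=True)
class RunResult:
    test_macro_f1: float
    valid_macro_f1: float
    intra_distance: float
    inter_distance: float
    test_per_class_f1: tuple[float, ...]
    test_probs_key: tuple[int, int, float, float, float]  # cache key for probs


_PROBS: dict = {}


@lru_cache(maxsize=None)
def trained_run(
    corpus_seed: int,
    run_seed: int,
    gamma: float = 2.0,
    mu: float = 1.0,
    fraction: float = 1.0,
):
    """Train one benchmark model; returns a RunResult (probs cached aside)."""
    records, schema = benchmark_corpus(corpus_seed)
    if fraction < 1.0:
        records = subsample_training_set(records, fraction, seed=run_seed)
    enc = EncoderConfig(encoder_id=f"char-emb-{run_seed}", seed=run_seed)
    loss_cfg = LossConfig(gamma=gamma, mu=mu)
    train_cfg = TrainConfig(seed=run_seed)
    trained = train_single_model(records, schema, enc, None, loss_cfg, train_cfg)
    test = split_records(records, "test")
    texts = [r.text for r in test]
    y = np.array([r.label for r in test])
    probs = trained.predict_proba(texts)
    report = compute_metrics(confusion_counts(y, probs.argmax(axis=1), schema.n))
    intra, inter = mean_pairwise_distances(trained.features(texts), y)
    key = (corpus_seed, run_seed, gamma, mu, fraction)
    _PROBS[key] = (probs, y)
    return RunResult(
        test_macro_f1=report.macro_f1,
        valid_macro_f1=max(trained.history.valid_macro_f1),
        intra_distance=intra,
        inter_distance=inter,
        test_per_class_f1=tuple(report.per_class["f1"]),
        test_probs_key=key,
    )


def run_probs(result: RunResult):
    """Test-split (probability matrix, labels) of a cached run."""
    return _PROBS[result.test_probs_key]


@pytest.fixture(scope="session")
def tiny_corpus():
    """Small separable 4-class corpus for fast training tests."""
    spec = SyntheticSpec(
        n_classes=4,
        total_samples=240,
        imbalance_exponent=0.5,
        noise_rate=0.0,
        seed=7,
    )
    return generate_synthetic_corpus(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
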