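"""Model/Results interface over the ensemble pipeline.

`EnsembleTextModel` is constructed from a labeled corpus (records + schema,
or a DataFrame with text/label/split columns); `fit()` trains K diverse-seed
single models and returns an `EnsembleTextResults` carrying the members,
their training histories, test-split metrics for members and ensemble, the
intra/inter-class feature-distance diagnostics, and a `summary()` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .corpus import CategorySchema, LabeledText, split_records
from .encoder import EncoderConfig
from .ensemble import EnsembleOutput, predict_ensemble
from .evaluate import MetricReport, compare_models, compute_metrics, confusion_counts
from .losses import LossConfig, feature_distance
from .model import ModelConfig
from .train import TrainConfig, TrainedModel, train_single_model


class EnsembleTextModel:
    """Soft-voting ensemble of character-level convolutional classifiers.

    Parameters
    ----------
    records, schema
        The labeled corpus with train/valid/test split tags.
    n_members
        Ensemble size K (default 5).  Member i trains on an independently
        seeded embedding table, the ensemble's source of diversity.
    """

    def __init__(
        self,
        records: list[LabeledText],
        schema: CategorySchema,
        n_members: int = 5,
        model_config: ModelConfig | None = None,
        loss_config: LossConfig | None = None,
        train_config: TrainConfig | None = None,
        embedding_dim: int = 16,
        max_length: int = 64,
    ) -> None:
        if n_members < 1:
            raise ValueError("n_members must be >= 1")
        self.records = list(records)
        self.schema = schema
        self.n_members = n_members
        self.model_config = model_config or ModelConfig(n_classes=schema.n)
        self.loss_config = loss_config or LossConfig()
        self.train_config = train_config or TrainConfig()
        self.embedding_dim = embedding_dim
        self.max_length = max_length

    @classmethod
    def from_dataframe(
        cls, frame: pd.DataFrame, **kwargs
    ) -> "EnsembleTextModel":
        """Build from a DataFrame with columns text, label, optional split."""
        if "text" not in frame or "label" not in frame:
            raise ValueError("DataFrame needs 'text' and 'label' columns")
        labels = frame["label"].astype(str)
        schema = CategorySchema.from_labels(labels)
        splits = (
            frame["split"] if "split" in frame else pd.Series("train", index=frame.index)
        )
        records = [
            LabeledText(text=t, label=schema.index(l), split=s)
            for t, l, s in zip(frame["text"], labels, splits)
        ]
        return cls(records, schema, **kwargs)

    def fit(self, seed: int = 0) -> "EnsembleTextResults":
        """Train all K members and evaluate members and ensemble on test.

        Member i uses encoder seed ``seed + i`` and shares the optimizer
        seed, so reruns with the same seed reproduce the results exactly.
        """
        members: list[TrainedModel] = []
        for i in range(self.n_members):
            enc = EncoderConfig(
                embedding_dim=self.embedding_dim,
                max_length=self.max_length,
                encoder_id=f"char-emb-{i}",
                seed=seed + i,
            )
            members.append(
                train_single_model(
                    self.records,
                    self.schema,
                    enc,
                    self.model_config,
                    self.loss_config,
                    TrainConfig(
                        learning_rate=self.train_config.learning_rate,
                        batch_size=self.train_config.batch_size,
                        epochs=self.train_config.epochs,
                        seed=seed + i,
                        weight_decay=self.train_config.weight_decay,
                    ),
                )
            )
        return EnsembleTextResults(model=self, members=members, seed=seed)


@dataclass
class EnsembleTextResults:
    """Fitted ensemble: members, diagnostics, and summary statistics."""

    model: EnsembleTextModel
    members: list[TrainedModel]
    seed: int
    _cache: dict = field(default_factory=dict, repr=False)

    # -- predictions -------------------------------------------------------

    def predict(self, texts: list[str]) -> np.ndarray:
        return self.vote(texts).predictions

    def vote(self, texts: list[str]) -> EnsembleOutput:
        return predict_ensemble(self.members, texts)

    # -- evaluation --------------------------------------------------------

    def _test_split(self) -> tuple[list[str], np.ndarray]:
        test = split_records(self.model.records, "test")
        if not test:
            raise ValueError("corpus has no test split")
        return [r.text for r in test], np.array([r.label for r in test])

    def member_reports(self) -> list[MetricReport]:
        """Test-split metric reports of the individual members."""
        if "member_reports" not in self._cache:
            texts, y = self._test_split()
            reports = []
            for m in self.members:
                pred = m.predict(texts)
                reports.append(compute_metrics(confusion_counts(y, pred, self.model.schema.n)))
            self._cache["member_reports"] = reports
        return self._cache["member_reports"]

    def ensemble_report(self) -> MetricReport:
        """Test-split metric report of the soft-voted ensemble."""
        if "ensemble_report" not in self._cache:
            texts, y = self._test_split()
            pred = self.vote(texts).predictions
            self._cache["ensemble_report"] = compute_metrics(
                confusion_counts(y, pred, self.model.schema.n)
            )
        return self._cache["ensemble_report"]

    def compare_to_members(self) -> pd.DataFrame:
        """Paired t-test of ensemble vs each member on per-class F1."""
        ens_f1 = self.ensemble_report().per_class["f1"].to_numpy()
        rows = []
        for m, rep in zip(self.members, self.member_reports()):
            t, p = compare_models(ens_f1, rep.per_class["f1"].to_numpy())
            rows.append(
                {
                    "member": m.encoder_config.encoder_id,
                    "member_macro_f1": rep.macro_f1,
                    "t_statistic": t,
                    "p_value": p,
                }
            )
        return pd.DataFrame(rows)

    def feature_distance_diagnostics(self) -> dict[str, float]:
        """Mean intra- vs inter-class feature distance on the test split.

        Metric learning succeeds when the intra mean falls below the inter
        mean: same-class texts cluster, different classes separate.
        Averaged over members.
        """
        texts, y = self._test_split()
        intra_means, inter_means = [], []
        for m in self.members:
            reps = m.features(texts)
            intra, inter = mean_pairwise_distances(reps, y)
            intra_means.append(intra)
            inter_means.append(inter)
        return {
            "mean_intra_class_distance": float(np.mean(intra_means)),
            "mean_inter_class_distance": float(np.mean(inter_means)),
        }

    # -- presentation ------------------------------------------------------

    def summary(self) -> str:
        """Plain-text summary table in the spirit of a regression summary."""
        reps = self.member_reports()
        ens = self.ensemble_report()
        lines = [
            "Ensemble text classification results",
            "=" * 60,
            f"categories: {self.model.schema.n}    members: {len(self.members)}"
            f"    seed: {self.seed}",
            f"loss: focal(gamma={self.model.loss_config.gamma})"
            f" + mu={self.model.loss_config.mu} * metric"
            f"(lambda={self.model.loss_config.lambda_},"
            f" m={self.model.loss_config.margin})",
            "-" * 60,
            f"{'model':<16}{'accuracy':>10}{'macro P':>10}{'macro R':>10}{'macro F1':>10}",
        ]
        for m, rep in zip(self.members, reps):
            lines.append(
                f"{m.encoder_config.encoder_id:<16}{rep.accuracy:>10.4f}"
                f"{rep.macro_precision:>10.4f}{rep.macro_recall:>10.4f}"
                f"{rep.macro_f1:>10.4f}"
            )
        lines.append("-" * 60)
        lines.append(
            f"{'soft-vote':<16}{ens.accuracy:>10.4f}{ens.macro_precision:>10.4f}"
            f"{ens.macro_recall:>10.4f}{ens.macro_f1:>10.4f}"
        )
        gain = ens.macro_f1 - float(np.mean([r.macro_f1 for r in reps]))
        lines.append(f"macro-F1 gain over member mean: {gain:+.4f}")
        dist = self.feature_distance_diagnostics()
        lines.append(
            f"feature distances (test): intra {dist['mean_intra_class_distance']:.4f}"
            f" < inter {dist['mean_inter_class_distance']:.4f}"
            if dist["mean_intra_class_distance"] < dist["mean_inter_class_distance"]
            else f"feature distances (test): intra {dist['mean_intra_class_distance']:.4f}"
            f" >= inter {dist['mean_inter_class_distance']:.4f}"
        )
        lines.append("=" * 60)
        return "\n".join(lines)


def mean_pairwise_distances(
    representations: np.ndarray, labels: np.ndarray
) -> tuple[float, float]:
    """Mean same-class and cross-class feature distances over all pairs."""
    reps = np.asarray(representations, dtype=float)
    labels = np.asarray(labels)
    d = reps.shape[1]
    sq = (
        (reps * reps).sum(axis=1)[:, None]
        + (reps * reps).sum(axis=1)[None, :]
        - 2.0 * reps @ reps.T
    )
    dmat = np.maximum(sq, 0.0) / d
    same = labels[:, None] == labels[None, :]
    iu = np.triu_indices(len(labels), k=1)
    same_u = same[iu]
    return float(dmat[iu][same_u].mean()), float(dmat[iu][~same_u].mean())
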