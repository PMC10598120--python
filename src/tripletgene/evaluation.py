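"""Downstream classification on embeddings and the cross-validation harness.

Metrics follow the rank (Mann-Whitney) formulation of AUC with ties counted
one half, the interpolation-free step-wise AUPRC, and F1 at a fixed 0.5
probability threshold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, f1_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from ._network import Adam
from .datasets import ExpressionDataset, FeatureScaler
from .model import Classifier, ClassifierSpec, EmbeddingModelSpec, build_classifier
from .synthetic import stratified_indices
from .training import TrainingConfig, train_embedding

__all__ = [
    "EvaluationReport",
    "train_classifier",
    "auc",
    "auprc",
    "f1",
    "cross_validate",
]


def _check_two_classes(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    return labels


def auc(scores, labels) -> float:
    """P(random positive outscores random negative), ties counted 1/2."""
    labels = _check_two_classes(labels)
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def auprc(scores, labels) -> float:
    """Step-wise (interpolation-free) area under the precision-recall curve."""
    labels = _check_two_classes(labels)
    return float(average_precision_score(labels, np.asarray(scores, dtype=float)))


def f1(scores, labels, threshold: float = 0.5) -> float:
    """Harmonic mean of precision and recall at a fixed score threshold.

    Zero when precision + recall is zero (no predicted or no true positives).
    """
    labels = _check_two_classes(labels)
    pred = (np.asarray(scores, dtype=float) >= threshold).astype(int)
    return float(f1_score(labels, pred, zero_division=0))


def train_classifier(
    embeddings: np.ndarray,
    labels,
    spec: ClassifierSpec | None = None,
    lr: float = 0.01,
    max_epochs: int = 300,
    seed: int = 0,
) -> Classifier:
    """Fit the one-layer sigmoid head on embeddings with full-batch Adam.

    Deterministic given the seed (Xavier init of the head). Raises on
    single-class input.
    """
    embeddings = np.asarray(embeddings, dtype=float)
    labels = _check_two_classes(labels)
    if spec is None:
        spec = ClassifierSpec(input_dim=embeddings.shape[1], init_seed=seed)
    g = build_classifier(spec)
    opt = Adam(g.params, lr=lr)
    for _ in range(max_epochs):
        _, grads = g.head.bce_grad(embeddings, labels)
        opt.step(grads)
    return g


@dataclass
class EvaluationReport:
    """Per-fold and aggregate AUC / AUPRC / F1 with the fold assignments."""

    fold_metrics: list[dict[str, float]]
    fold_assignments: list[np.ndarray]
    config: dict[str, Any] = field(default_factory=dict)

    def summary(self) -> dict[str, dict[str, float]]:
        out: dict[str, dict[str, float]] = {}
        for metric in ("auc", "auprc", "f1"):
            vals = np.array([m[metric] for m in self.fold_metrics])
            out[metric] = {"mean": float(vals.mean()), "sd": float(vals.std(ddof=1))}
        return out

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.fold_metrics)
        df.insert(0, "fold", range(len(self.fold_metrics)))
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")

    def to_json(self, path) -> None:
        payload = {"summary": self.summary(), "per_fold": self.fold_metrics,
                   "config": self.config}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")


def cross_validate(
    ds: ExpressionDataset,
    k_folds: int,
    spec: EmbeddingModelSpec,
    train_cfg: TrainingConfig,
    seed: int = 0,
    classifier_lr: float = 0.01,
    classifier_epochs: int = 300,
) -> EvaluationReport:
    """Stratified k-fold evaluation of the full embed-then-classify pipeline.

    Per fold: feature standardization is fit on the training portion only and
    applied to the held-out fold; 20% of the training portion becomes the
    validation set for triplet early stopping; the embedding is trained, the
    classifier head fit on the training embeddings, and AUC / AUPRC / F1
    measured on the untouched test fold.
    """
    labels = ds.require_labels()
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    fold_metrics: list[dict[str, float]] = []
    assignments: list[np.ndarray] = []
    for fold, (train_idx, test_idx) in enumerate(skf.split(ds.values, labels)):
        scaler = FeatureScaler().fit(ds.values[train_idx])
        ds_scaled = ExpressionDataset(
            scaler.transform(ds.values),
            ds.gene_ids,
            ds.sample_ids,
            labels=labels,
            n_clinical=ds.n_clinical,
        )
        inner = stratified_indices(labels[train_idx], (0.8, 0.2), seed=seed + fold)
        tr = ds_scaled.subset(train_idx[inner[0]])
        va = ds_scaled.subset(train_idx[inner[1]])
        te = ds_scaled.subset(test_idx)

        fold_cfg = TrainingConfig(**{**train_cfg.__dict__, "seed": train_cfg.seed + fold})
        f, _ = train_embedding(tr, va, spec, fold_cfg)
        g = train_classifier(
            f.embed(tr), tr.labels, lr=classifier_lr,
            max_epochs=classifier_epochs, seed=fold_cfg.seed,
        )
        scores = g.predict_proba(f.embed(te))
        fold_metrics.append(
            {"auc": auc(scores, te.labels), "auprc": auprc(scores, te.labels),
             "f1": f1(scores, te.labels)}
        )
        assignments.append(test_idx)
    covered = np.sort(np.concatenate(assignments))
    assert np.array_equal(covered, np.arange(ds.n_samples)), "folds must cover all samples"
    return EvaluationReport(
        fold_metrics=fold_metrics,
        fold_assignments=assignments,
        config={
            "k_folds": k_folds,
            "seed": seed,
            "embedding": {k: v for k, v in spec.__dict__.items()},
            "training": {k: (v.__dict__ if hasattr(v, "__dict__") else v)
                         for k, v in train_cfg.__dict__.items()},
        },
    )
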