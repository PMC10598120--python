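"""Embedding training: per-epoch online strict semi-hard mining, joint loss,
Adam updates, dual early stopping and category-trajectory logging.

Each epoch: (1) embed every training sample with the current weights;
(2) categorize all N training triplets; (3) keep the strict semi-hard ones
(semi-hard in both anchor orientations); (4) optionally add up to
``hard_supplement_k`` least-loss hard triplets; (5) shuffle the retained set
and run Adam mini-batch updates on the mean joint loss; (6) monitor the mean
joint loss over the validation triplet set's strict semi-hard subset.

Training stops when the validation loss has not decreased for ``patience``
epochs, when the retained-triplet count drops below ``min_semi_hard`` (the
embedding has pushed nearly everything out of the ambiguous band), or at
``max_epochs``; the weights of the best-validation epoch are restored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from ._network import Adam
from .datasets import ExpressionDataset
from .losses import LossConfig, batch_loss_grad, per_triplet_losses
from .model import EmbeddingModelSpec, EmbeddingNet, build_embedding_model
from .triplets import (
    CategoryCounts,
    TripletSet,
    build_triplets,
    categorize_all,
    select_hard_supplement,
    semi_hard_filter,
    strict_semi_hard_filter,
)

__all__ = ["TrainingConfig", "TrainingHistory", "HistoryEntry",
           "train_embedding", "validation_loss"]

LEARNING_RATE_GRID = (0.1, 0.05, 0.01, 0.005)


@dataclass
class TrainingConfig:
    """Hyperparameters of the embedding training loop.

    n_triplets is the size N of the random balanced training triplet set
    (50,000 at the AD-cohort scale; scale down with the data).
    min_semi_hard is the retained-count floor below which training stops.
    """

    learning_rate: float = 0.01
    batch_size: int = 300
    n_triplets: int = 50_000
    val_n_triplets: int | None = None  # default: n_triplets // 3
    patience: int = 30
    min_semi_hard: int = 50
    max_epochs: int = 200
    hard_supplement_k: int = 0
    strict_mining: bool = True  # False: conventional semi-hard mining (no switching check)
    mine_per_batch: bool = False
    seed: int = 0
    loss: LossConfig = field(default_factory=LossConfig)

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.min_semi_hard < 0 or self.hard_supplement_k < 0:
            raise ValueError("counts must be non-negative")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be non-negative")


class HistoryEntry(NamedTuple):
    counts: CategoryCounts
    train_loss: float
    val_loss: float


@dataclass
class TrainingHistory:
    """Per-epoch category counts and losses, plus why training stopped."""

    entries: list[HistoryEntry] = field(default_factory=list)
    stop_reason: str = "max_epochs"  # one of patience, min_semi_hard, max_epochs
    best_epoch: int = 0

    def __len__(self) -> int:
        return len(self.entries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": [e.counts.epoch for e in self.entries],
                "easy": [e.counts.easy for e in self.entries],
                "semi_hard": [e.counts.semi_hard for e in self.entries],
                "hard": [e.counts.hard for e in self.entries],
                "strict_semi_hard": [e.counts.strict_semi_hard for e in self.entries],
                "train_loss": [e.train_loss for e in self.entries],
                "val_loss": [e.val_loss for e in self.entries],
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")

    def plot(self, path) -> None:
        """Render the category-count trajectories to an image file."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        df = self.to_frame()
        fig, ax = plt.subplots(figsize=(6, 4))
        for col in ("easy", "semi_hard", "hard", "strict_semi_hard"):
            ax.plot(df["epoch"], df[col], label=col.replace("_", " "))
        ax.set_xlabel("epoch")
        ax.set_ylabel("triplet count")
        ax.legend()
        fig.tight_layout()
        fig.savefig(path)
        plt.close(fig)


class _RemappedTriplets(NamedTuple):
    """Triplet index arrays remapped onto a compact sample subset."""

    anchors: np.ndarray
    positives: np.ndarray
    negatives: np.ndarray


def _batch_step(
    f: EmbeddingNet,
    X_aug: np.ndarray,
    ts: TripletSet,
    batch_idx: np.ndarray,
    cfg: TrainingConfig,
    opt: Adam,
) -> tuple[float, int]:
    """One Adam update on a mini-batch of triplets; returns (loss, n_used)."""
    a = ts.anchors[batch_idx]
    p = ts.positives[batch_idx]
    n = ts.negatives[batch_idx]
    samples, inv = np.unique(np.concatenate([a, p, n]), return_inverse=True)
    cache: dict = {}
    E_sub = f.embed_rows(X_aug[samples], cache=cache)
    B = len(batch_idx)
    local = _RemappedTriplets(inv[:B], inv[B : 2 * B], inv[2 * B :])
    use = np.arange(B)
    if cfg.mine_per_batch:
        miner = strict_semi_hard_filter if cfg.strict_mining else semi_hard_filter
        keep = miner(
            E_sub,
            TripletSet(local.anchors, local.positives, local.negatives, 0, 0, -1),
            cfg.loss.margin,
            cfg.loss.metric,
        )
        if len(keep) == 0:
            return 0.0, 0
        use = keep
    loss, dE = batch_loss_grad(E_sub, use, local, cfg.loss)
    grads = f.core.backward(cache, dE)
    opt.step(grads)
    return loss, len(use)


def validation_loss(
    f: EmbeddingNet,
    ds_val: ExpressionDataset,
    val_triplets: TripletSet,
    cfg: TrainingConfig,
) -> float:
    """Mean joint loss over the validation set's strict semi-hard triplets.

    An empty strict set means every validation triplet is resolved (easy or
    unambiguously hard both ways); the loss is defined as 0 then so a fully
    learned embedding can terminate via patience.
    """
    E = f.embed(ds_val)
    miner = strict_semi_hard_filter if cfg.strict_mining else semi_hard_filter
    keep = miner(E, val_triplets, cfg.loss.margin, cfg.loss.metric)
    if len(keep) == 0:
        return 0.0
    losses = per_triplet_losses(
        E,
        val_triplets.anchors[keep],
        val_triplets.positives[keep],
        val_triplets.negatives[keep],
        cfg.loss,
    )
    return float(losses.mean())


def train_embedding(
    ds_train: ExpressionDataset,
    ds_val: ExpressionDataset,
    spec: EmbeddingModelSpec,
    cfg: TrainingConfig,
) -> tuple[EmbeddingNet, TrainingHistory]:
    """Train the embedding function with online strict semi-hard mining.

    Deterministic for fixed data, spec and config: triplet construction,
    initialization and the per-epoch shuffles all derive from the seeds.
    Returns the network restored to the best-validation-epoch weights and the
    full per-epoch :class:`TrainingHistory`.
    """
    labels = ds_train.require_labels()
    ds_val.require_labels()
    train_ts = build_triplets(labels, cfg.n_triplets, seed=cfg.seed)
    n_val = cfg.val_n_triplets
    if n_val is None:
        n_val = max(2, (cfg.n_triplets // 3) // 2 * 2)
    val_ts = build_triplets(ds_val.labels, n_val, seed=cfg.seed + 1)

    f = build_embedding_model(spec)
    opt = Adam(f.params, lr=cfg.learning_rate)
    X_aug = f.augment(ds_train)

    history = TrainingHistory()
    best_val = np.inf
    best_params = f.core.copy_params()
    wait = 0

    for epoch in range(cfg.max_epochs):
        E = f.embed_rows(X_aug)
        _, counts = categorize_all(E, train_ts, cfg.loss.margin, cfg.loss.metric, epoch)
        miner = strict_semi_hard_filter if cfg.strict_mining else semi_hard_filter
        retained = miner(E, train_ts, cfg.loss.margin, cfg.loss.metric)
        if cfg.hard_supplement_k > 0:
            extra = select_hard_supplement(
                E, train_ts, cfg.loss.margin, cfg.hard_supplement_k, cfg.loss
            )
            retained = np.concatenate([retained, extra])

        if len(retained) == 0 and cfg.min_semi_hard == 0 and epoch == 0:
            raise RuntimeError(
                "no strict semi-hard triplets at epoch 0 "
                f"(easy={counts.easy}, semi_hard={counts.semi_hard}, "
                f"hard={counts.hard}); nothing to train on"
            )

        if len(retained) < cfg.min_semi_hard:
            if len(retained) > 0:
                train_loss = float(
                    per_triplet_losses(
                        E,
                        train_ts.anchors[retained],
                        train_ts.positives[retained],
                        train_ts.negatives[retained],
                        cfg.loss,
                    ).mean()
                )
            else:
                train_loss = 0.0
            val_loss = validation_loss(f, ds_val, val_ts, cfg)
            history.entries.append(HistoryEntry(counts, train_loss, val_loss))
            if val_loss < best_val:
                best_val, best_params = val_loss, f.core.copy_params()
                history.best_epoch = epoch
            history.stop_reason = "min_semi_hard"
            break

        rng = np.random.default_rng([cfg.seed, epoch])
        order = rng.permutation(retained)
        loss_sum, n_used = 0.0, 0
        for start in range(0, len(order), cfg.batch_size):
            batch = order[start : start + cfg.batch_size]
            loss, used = _batch_step(f, X_aug, train_ts, batch, cfg, opt)
            loss_sum += loss * used
            n_used += used
        train_loss = loss_sum / n_used if n_used else 0.0

        val_loss = validation_loss(f, ds_val, val_ts, cfg)
        history.entries.append(HistoryEntry(counts, train_loss, val_loss))

        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_params = f.core.copy_params()
            history.best_epoch = epoch
            wait = 0
        else:
            wait += 1
            if wait >= cfg.patience:
                history.stop_reason = "patience"
                break
    else:
        history.stop_reason = "max_epochs"

    f.core.set_params(best_params)
    return f, history
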