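"""Synthetic two-class expression data with a controllable differential signal.

Emulates the regime of the real cohorts the method targets — far more genes
than samples, a modest subset of class-informative genes, optional clinical
covariates — without any external download. Background genes are standard
normal in both classes; the first ``n_informative`` gene columns are shifted
by ``effect_size`` standard deviations in the disease class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets import ExpressionDataset, attach_clinical

__all__ = ["SyntheticConfig", "generate", "train_val_test_split", "stratified_indices"]


@dataclass
class SyntheticConfig:
    """Parameters of the two-class Gaussian expression generator.

    effect_size is the mean shift, in SD units, applied to the informative
    genes of class 1; class_balance is the fraction of class-1 samples.
    Informative genes are always the first ``n_informative`` columns (named
    with an ``inf_`` prefix) so tests can verify signal placement.
    """

    n_samples: int = 200
    n_genes: int = 1000
    n_informative: int = 50
    effect_size: float = 1.5
    class_balance: float = 0.5
    clinical: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative > self.n_genes:
            raise ValueError("n_informative cannot exceed n_genes")
        if self.n_samples < 4:
            raise ValueError("need at least 4 samples")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        if not 0 < self.class_balance < 1:
            raise ValueError("class_balance must lie in (0, 1)")


def generate(config: SyntheticConfig) -> ExpressionDataset:
    """Draw a labeled expression dataset, fully reproducible from the seed.

    Clinical covariates, when enabled: age ~ Normal(70, 5) for controls and
    Normal(75, 5) for cases, sex ~ Bernoulli(0.5), marital ~ uniform over the
    integer codes {-2..2}; they are appended (standardized) as trailing
    clinical columns.
    """
    rng = np.random.default_rng(config.seed)
    n, p = config.n_samples, config.n_genes
    n1 = int(round(n * config.class_balance))
    n1 = min(max(n1, 2), n - 2)  # both classes need >= 2 samples for triplets
    labels = np.zeros(n, dtype=int)
    labels[:n1] = 1
    rng.shuffle(labels)

    values = rng.standard_normal((n, p))
    values[labels == 1, : config.n_informative] += config.effect_size
    gene_ids = [
        f"inf_{j:04d}" if j < config.n_informative else f"gene_{j:04d}"
        for j in range(p)
    ]
    sample_ids = [f"S{i:04d}" for i in range(n)]
    ds = ExpressionDataset(values, gene_ids, sample_ids, labels=labels)

    if config.clinical:
        age = np.where(labels == 1, 75.0, 70.0) + 5.0 * rng.standard_normal(n)
        sex = rng.integers(0, 2, size=n).astype(float)
        marital = rng.integers(-2, 3, size=n).astype(float)
        ds = attach_clinical(
            ds,
            np.column_stack([age, sex, marital]),
            feature_names=["age", "sex", "marital"],
        )
    return ds


def stratified_indices(
    labels: np.ndarray, fractions: tuple[float, ...], seed: int
) -> list[np.ndarray]:
    """Split sample indices into label-stratified parts of given fractions.

    Within each class, counts are apportioned by the largest-remainder rule so
    the split sizes are exact whenever the fractions divide the class counts.
    """
    labels = np.asarray(labels)
    fractions = tuple(float(f) for f in fractions)
    if any(f < 0 for f in fractions) or abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must be non-negative and sum to 1")
    rng = np.random.default_rng(seed)
    parts: list[list[int]] = [[] for _ in fractions]
    for cls in np.unique(labels):
        idx = np.where(labels == cls)[0]
        rng.shuffle(idx)
        m = len(idx)
        quotas = [f * m for f in fractions]
        counts = [int(np.floor(q)) for q in quotas]
        remainders = np.array(quotas) - np.array(counts)
        for k in np.argsort(-remainders, kind="stable")[: m - sum(counts)]:
            counts[k] += 1
        start = 0
        for k, c in enumerate(counts):
            parts[k].extend(idx[start : start + c].tolist())
            start += c
    return [np.array(sorted(p), dtype=int) for p in parts]


def train_val_test_split(
    ds: ExpressionDataset,
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> tuple[ExpressionDataset, ExpressionDataset, ExpressionDataset]:
    """Stratified, disjoint, covering three-way split, reproducible from seed.

    Raises if any split would receive fewer than two samples of either class
    (triplet construction needs two).
    """
    labels = ds.require_labels()
    if len(fractions) != 3:
        raise ValueError("fractions must be a (train, val, test) triple")
    parts = stratified_indices(labels, fractions, seed)
    names = ("train", "validation", "test")
    for name, idx in zip(names, parts):
        sub = labels[idx]
        for cls in (0, 1):
            if int((sub == cls).sum()) < 2:
                raise ValueError(
                    f"{name} split has fewer than 2 samples of class {cls}"
                )
    train, val, test = (ds.subset(idx) for idx in parts)
    return train, val, test
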