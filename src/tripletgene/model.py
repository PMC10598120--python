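"""The 1D convolutional embedding network and the downstream classifier head.

The embedding function maps one expression (+ clinical) row to a
``d_embedding``-dimensional vector. Genes are cut into consecutive windows of
``kernel_size`` values; the full clinical vector is replicated after *every*
window so each kernel computation sees the covariates; the convolution stride
equals the effective window length (kernel_size + n_clinical), so windows do
not overlap and each conv output position summarizes one gene window.

Architecture: conv (n_filters channels) -> ReLU -> max pool -> flatten ->
fully connected -> (optional) L2 normalization. All weights are
Xavier-initialized from ``init_seed``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from ._network import Conv1DEmbedder, LinearSigmoid
from .datasets import ExpressionDataset

__all__ = [
    "EmbeddingModelSpec",
    "ClassifierSpec",
    "EmbeddingNet",
    "Classifier",
    "interleave_clinical",
    "interleave_matrix",
    "build_embedding_model",
    "embed",
    "build_classifier",
    "classify",
    "save_checkpoint",
    "load_checkpoint",
]

EMBEDDING_DIM_GRID = (30, 60, 90, 120, 150)


def default_kernel_size(n_genes: int) -> int:
    """About 1% of the gene count, at least 1."""
    return max(1, int(round(0.01 * n_genes)))


@dataclass
class EmbeddingModelSpec:
    """Architecture of the embedding network.

    kernel_size defaults to ~1% of n_genes. normalize_embedding pins the
    output on the unit sphere — the standard convention for margin-based
    triplet losses, which otherwise have no fixed scale for the margin.
    """

    n_genes: int
    n_clinical: int = 0
    kernel_size: int | None = None
    n_filters: int = 8
    pool_size: int = 2
    embedding_dim: int = 30
    init_seed: int = 0
    normalize_embedding: bool = True

    def __post_init__(self) -> None:
        if self.kernel_size is None:
            self.kernel_size = default_kernel_size(self.n_genes)
        if self.kernel_size < 1:
            raise ValueError("kernel_size must be >= 1")
        if self.n_genes < 1 or self.n_clinical < 0:
            raise ValueError("invalid feature counts")
        if self.embedding_dim < 1:
            raise ValueError("embedding_dim must be >= 1")
        if self.n_filters < 1 or self.pool_size < 1:
            raise ValueError("n_filters and pool_size must be >= 1")

    @property
    def n_windows(self) -> int:
        return -(-self.n_genes // self.kernel_size)  # ceil

    @property
    def effective_window(self) -> int:
        """Conv window and stride: gene window plus interleaved clinical block."""
        return self.kernel_size + self.n_clinical

    @property
    def augmented_length(self) -> int:
        return self.n_windows * self.effective_window


def interleave_clinical(
    gene_row: np.ndarray, clinical_row: np.ndarray, k: int
) -> np.ndarray:
    """Insert the full clinical vector after every k-gene window.

    The last window is zero-padded to length k. Output length is
    ``ceil(n_genes / k) * (k + n_clinical)``.
    """
    gene_row = np.asarray(gene_row, dtype=float).ravel()
    clinical_row = np.asarray(clinical_row, dtype=float).ravel()
    return interleave_matrix(gene_row[None, :], clinical_row[None, :], k)[0]


def interleave_matrix(
    genes: np.ndarray, clinical: np.ndarray, k: int
) -> np.ndarray:
    """Row-wise :func:`interleave_clinical` over whole matrices."""
    genes = np.asarray(genes, dtype=float)
    clinical = np.asarray(clinical, dtype=float)
    if k < 1:
        raise ValueError("kernel size must be >= 1")
    n, p = genes.shape
    nw = -(-p // k)
    padded = np.zeros((n, nw * k))
    padded[:, :p] = genes
    windows = padded.reshape(n, nw, k)
    clin = np.broadcast_to(clinical[:, None, :], (n, nw, clinical.shape[1]))
    return np.concatenate([windows, clin], axis=2).reshape(n, nw * (k + clinical.shape[1]))


class EmbeddingNet:
    """The embedding function f: expression (+ clinical) row -> R^d."""

    def __init__(self, spec: EmbeddingModelSpec):
        self.spec = spec
        self.core = Conv1DEmbedder(
            window=spec.effective_window,
            n_windows=spec.n_windows,
            n_filters=spec.n_filters,
            pool_size=spec.pool_size,
            embedding_dim=spec.embedding_dim,
            init_seed=spec.init_seed,
            normalize=spec.normalize_embedding,
        )

    @property
    def params(self) -> dict[str, np.ndarray]:
        return self.core.params

    def augment(self, ds: ExpressionDataset) -> np.ndarray:
        """Interleaved input rows for a dataset (shape check included)."""
        expected = self.spec.n_genes + self.spec.n_clinical
        if ds.n_features != expected:
            raise ValueError(
                f"dataset has {ds.n_features} features; model expects {expected} "
                f"({self.spec.n_genes} genes + {self.spec.n_clinical} clinical)"
            )
        genes = ds.values[:, : self.spec.n_genes]
        clinical = ds.values[:, self.spec.n_genes :]
        return interleave_matrix(genes, clinical, self.spec.kernel_size)

    def embed_rows(self, X_aug: np.ndarray, cache: dict | None = None) -> np.ndarray:
        return self.core.forward(X_aug, cache=cache)

    def embed(self, ds: ExpressionDataset) -> np.ndarray:
        out = self.core.forward(self.augment(ds))
        if not np.all(np.isfinite(out)):
            raise FloatingPointError("non-finite embedding values")
        return out


def build_embedding_model(spec: EmbeddingModelSpec) -> EmbeddingNet:
    """Initialized embedding network; identical weights for identical seeds."""
    return EmbeddingNet(spec)


def embed(f: EmbeddingNet, ds: ExpressionDataset) -> np.ndarray:
    """(n_samples, d_embedding) embedding matrix for a dataset."""
    return f.embed(ds)


@dataclass
class ClassifierSpec:
    """One fully connected layer from the embedding to a class-1 probability."""

    input_dim: int
    init_seed: int = 0

    def __post_init__(self) -> None:
        if self.input_dim < 1:
            raise ValueError("input_dim must be >= 1")


class Classifier:
    """Sigmoid-squashed linear head over embeddings."""

    def __init__(self, spec: ClassifierSpec):
        self.spec = spec
        self.head = LinearSigmoid(spec.input_dim, init_seed=spec.init_seed)

    @property
    def params(self) -> dict[str, np.ndarray]:
        return self.head.params

    def predict_proba(self, embeddings: np.ndarray) -> np.ndarray:
        embeddings = np.asarray(embeddings, dtype=float)
        if embeddings.ndim != 2 or embeddings.shape[1] != self.spec.input_dim:
            raise ValueError(
                f"embeddings of dimension {embeddings.shape} do not match "
                f"input_dim {self.spec.input_dim}"
            )
        return self.head.predict_proba(embeddings)


def build_classifier(spec: ClassifierSpec) -> Classifier:
    return Classifier(spec)


def classify(g: Classifier, embeddings: np.ndarray) -> np.ndarray:
    """Per-sample probability of class 1, each strictly inside (0, 1)."""
    p = g.predict_proba(embeddings)
    return np.clip(p, 1e-15, 1 - 1e-15)


def save_checkpoint(f: EmbeddingNet, path) -> None:
    """Single-file checkpoint: weights plus the spec needed to rebuild."""
    np.savez(
        path,
        spec=json.dumps(asdict(f.spec)),
        **{k: v for k, v in f.params.items()},
    )


def load_checkpoint(path) -> EmbeddingNet:
    with np.load(path, allow_pickle=False) as data:
        spec = EmbeddingModelSpec(**json.loads(str(data["spec"])))
        net = EmbeddingNet(spec)
        net.core.set_params({k: data[k] for k in net.params})
    return net
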