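"""Loading, validation and preprocessing of expression matrices and clinical tables.

The canonical in-memory container is :class:`ExpressionDataset`: a dense
``samples x features`` matrix of real numbers with per-sample binary labels.
Gene expression columns come first; encoded clinical covariates, when present,
occupy the trailing ``n_clinical`` columns so the embedding model can split
them off again for per-window interleaving.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionDataset",
    "ClinicalTable",
    "DEFAULT_MARITAL_MAPPING",
    "load_expression",
    "load_labels",
    "load_gene_groups",
    "collapse_duplicate_genes",
    "normalize_features",
    "FeatureScaler",
    "encode_clinical",
    "attach_clinical",
    "label_stage",
    "order_genes_by_groups",
]

#: Convention only: the source protocol fixes the range -2..2 and unknown -> 0
#: but not the per-category values. Override via ``encode_clinical(mapping=...)``.
DEFAULT_MARITAL_MAPPING: dict[str, int] = {
    "never married": -2,
    "divorced": -1,
    "unknown": 0,
    "widowed": 1,
    "married": 2,
}


@dataclass
class ExpressionDataset:
    """A samples x features expression matrix with optional labels.

    Parameters
    ----------
    values
        ``(n_samples, n_features)`` float matrix. Gene columns first, then
        ``n_clinical`` clinical columns.
    gene_ids
        Feature identifiers, one per column (clinical feature names included).
    sample_ids
        Unique per-sample identifiers.
    labels
        Optional per-sample binary class: 0 = control / early, 1 = disease /
        late. ``None`` until assigned by the caller.
    n_clinical
        Number of trailing clinical columns (0 if none).
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    labels: np.ndarray | None = None
    n_clinical: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        n, p = self.values.shape
        if len(self.gene_ids) != p:
            raise ValueError(
                f"{len(self.gene_ids)} feature ids for {p} columns"
            )
        if len(self.sample_ids) != n:
            raise ValueError(
                f"{len(self.sample_ids)} sample ids for {n} rows"
            )
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample IDs")
        if not 0 <= self.n_clinical <= p:
            raise ValueError("n_clinical out of range")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (n,):
                raise ValueError("labels length must match sample count")
            if not set(np.unique(self.labels)) <= {0, 1}:
                raise ValueError("labels must be binary 0/1")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def n_genes(self) -> int:
        """Number of gene columns (features minus clinical covariates)."""
        return self.n_features - self.n_clinical

    def require_labels(self) -> np.ndarray:
        if self.labels is None:
            raise ValueError("dataset has no labels")
        return self.labels

    def with_labels(self, labels: Sequence[int]) -> "ExpressionDataset":
        return replace(self, labels=np.asarray(labels, dtype=int))

    def subset(self, idx: np.ndarray) -> "ExpressionDataset":
        """Row subset preserving order of ``idx``."""
        idx = np.asarray(idx, dtype=int)
        return ExpressionDataset(
            values=self.values[idx],
            gene_ids=self.gene_ids,
            sample_ids=[self.sample_ids[i] for i in idx],
            labels=None if self.labels is None else self.labels[idx],
            n_clinical=self.n_clinical,
        )

    def to_tsv(self, path, delimiter: str = "\t") -> None:
        df = pd.DataFrame(self.values, index=self.sample_ids, columns=self.gene_ids)
        df.index.name = "sample_id"
        df.to_csv(path, sep=delimiter)


@dataclass
class ClinicalTable:
    """Per-sample covariates: age, sex, education, marital, stage.

    Columns may be partially present; ``columns`` maps a column name to a
    per-sample value sequence aligned with ``sample_ids``.
    """

    sample_ids: list[str]
    columns: dict[str, list] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sample_ids = list(self.sample_ids)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample IDs in clinical table")
        for name, col in self.columns.items():
            if len(col) != len(self.sample_ids):
                raise ValueError(f"clinical column {name!r} has wrong length")

    @classmethod
    def from_tsv(cls, path, delimiter: str = "\t") -> "ClinicalTable":
        df = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str)
        return cls(
            sample_ids=[str(s) for s in df.index],
            columns={c: df[c].tolist() for c in df.columns},
        )


def load_expression(path, delimiter: str = "\t") -> ExpressionDataset:
    """Parse a delimited expression table into an :class:`ExpressionDataset`.

    The first row is a header of feature identifiers; the first column holds
    sample identifiers. Labels are left unset — fill them from a label column
    or a separate two-column file (:func:`load_labels`).

    Raises
    ------
    ValueError
        On an empty file, a non-numeric data cell (named by sample and
        feature), or duplicate sample IDs.
    """
    try:
        df = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"empty expression file: {path}") from exc
    if df.shape[1] == 0:
        raise ValueError(f"expression file has no feature columns: {path}")
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        try:
            values[:, j] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError):
            bad = pd.to_numeric(df[col], errors="coerce")
            i = int(np.where(bad.isna() & df[col].notna())[0][0])
            raise ValueError(
                f"non-numeric cell at sample {df.index[i]!r}, feature {col!r}: "
                f"{df[col].iloc[i]!r}"
            ) from None
    return ExpressionDataset(
        values=values,
        gene_ids=[str(c) for c in df.columns],
        sample_ids=[str(s) for s in df.index],
    )


def load_labels(path, delimiter: str = "\t") -> dict[str, int]:
    """Read a two-column ``sample_id, label`` file into a mapping."""
    df = pd.read_csv(path, sep=delimiter, dtype=str)
    if df.shape[1] < 2:
        raise ValueError("label file needs two columns: sample_id, label")
    return {str(s): int(v) for s, v in zip(df.iloc[:, 0], df.iloc[:, 1])}


def load_gene_groups(path, delimiter: str = "\t") -> dict[str, list[str]]:
    """Read a two-column ``gene_id, group`` file into an ordered group map."""
    df = pd.read_csv(path, sep=delimiter, dtype=str)
    groups: dict[str, list[str]] = {}
    for g, grp in zip(df.iloc[:, 0], df.iloc[:, 1]):
        groups.setdefault(str(grp), []).append(str(g))
    return groups


def collapse_duplicate_genes(ds: ExpressionDataset) -> ExpressionDataset:
    """Replace repeated gene identifiers by the mean of their copies.

    First-occurrence column order is preserved. Idempotent: a second
    application is a no-op.
    """
    if ds.n_clinical != 0:
        raise ValueError("collapse duplicates before attaching clinical columns")
    order: dict[str, list[int]] = {}
    for j, g in enumerate(ds.gene_ids):
        order.setdefault(g, []).append(j)
    if all(len(cols) == 1 for cols in order.values()):
        return ds
    new_ids = list(order.keys())
    new_values = np.column_stack(
        [ds.values[:, cols].mean(axis=1) for cols in order.values()]
    )
    return ExpressionDataset(
        values=new_values,
        gene_ids=new_ids,
        sample_ids=ds.sample_ids,
        labels=ds.labels,
        n_clinical=0,
    )


class FeatureScaler:
    """Column-wise standardizer (mean 0, population SD 1).

    Fit on one matrix (typically the training fold) and apply to others so
    that no statistic leaks from validation/test data. Zero-variance columns
    are mapped to all-zeros rather than raising.
    """

    def __init__(self) -> None:
        self.mean_: np.ndarray | None = None
        self.scale_: np.ndarray | None = None

    def fit(self, values: np.ndarray) -> "FeatureScaler":
        values = np.asarray(values, dtype=float)
        self.mean_ = values.mean(axis=0)
        sd = values.std(axis=0)  # population SD (ddof=0)
        self.scale_ = np.where(sd > 0, sd, 1.0)
        self._zero_var = sd == 0
        return self

    def transform(self, values: np.ndarray) -> np.ndarray:
        if self.mean_ is None:
            raise RuntimeError("scaler not fitted")
        out = (np.asarray(values, dtype=float) - self.mean_) / self.scale_
        out[:, self._zero_var] = 0.0
        return out

    def fit_transform(self, values: np.ndarray) -> np.ndarray:
        return self.fit(values).transform(values)


def normalize_features(ds: ExpressionDataset) -> ExpressionDataset:
    """Standardize every feature column to mean 0, population SD 1.

    Statistics are computed on the given matrix; for leakage-free
    cross-validation fit a :class:`FeatureScaler` on the training fold
    instead. Zero-variance columns become all-zeros.
    """
    return replace(ds, values=FeatureScaler().fit_transform(ds.values))


def encode_clinical(
    table: ClinicalTable,
    mapping: Mapping[str, int] | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Encode clinical covariates into a numeric matrix.

    age and education pass through as reals; sex is encoded {0, 1} (error on
    more than two distinct values); marital status is mapped to integers in
    [-2, 2] with unrecognised / unknown categories mapped to 0. The ``stage``
    column is excluded (it is a label source, see :func:`label_stage`).

    Returns the matrix (rows in ``table.sample_ids`` order) and the feature
    names, in the table's column order.
    """
    if mapping is None:
        mapping = DEFAULT_MARITAL_MAPPING
    cols: list[np.ndarray] = []
    names: list[str] = []
    for name, raw in table.columns.items():
        key = name.lower()
        if key == "stage":
            continue
        if key == "sex":
            uniq = sorted({str(v) for v in raw})
            if len(uniq) > 2:
                raise ValueError(
                    f"sex column has {len(uniq)} distinct values {uniq}; "
                    "expected a binary encoding"
                )
            code = {u: i for i, u in enumerate(uniq)}
            cols.append(np.array([code[str(v)] for v in raw], dtype=float))
        elif key in ("marital", "marriage"):
            enc = []
            for v in raw:
                val = mapping.get(str(v).strip().lower(), 0)
                if not -2 <= val <= 2:
                    raise ValueError(f"marital code {val} outside [-2, 2]")
                enc.append(val)
            cols.append(np.array(enc, dtype=float))
        elif key in ("age", "education"):
            cols.append(np.array([float(v) for v in raw]))
        else:
            try:
                cols.append(np.array([float(v) for v in raw]))
            except (ValueError, TypeError):
                raise ValueError(
                    f"cannot encode non-numeric clinical column {name!r}"
                ) from None
        names.append(name)
    if not cols:
        return np.zeros((len(table.sample_ids), 0)), []
    return np.column_stack(cols), names


def attach_clinical(
    ds: ExpressionDataset,
    clinical: np.ndarray,
    feature_names: Sequence[str] | None = None,
    sample_ids: Sequence[str] | None = None,
) -> ExpressionDataset:
    """Append standardized clinical columns after the gene columns.

    The clinical matrix must have one row per sample in the same order as
    ``ds.sample_ids``; pass ``sample_ids`` to have the order verified.
    Columns are standardized (mean 0, population SD 1) before appending so
    they live on the same scale as normalized expression values.
    """
    clinical = np.asarray(clinical, dtype=float)
    if clinical.ndim != 2 or clinical.shape[0] != ds.n_samples:
        raise ValueError(
            f"clinical matrix has {clinical.shape[0] if clinical.ndim == 2 else '?'} "
            f"rows for {ds.n_samples} samples"
        )
    if sample_ids is not None and list(sample_ids) != ds.sample_ids:
        raise ValueError("clinical sample IDs do not match dataset order")
    if clinical.shape[1] == 0:
        return ds
    if feature_names is None:
        feature_names = [f"clinical_{j}" for j in range(clinical.shape[1])]
    if len(feature_names) != clinical.shape[1]:
        raise ValueError("feature_names length mismatch")
    scaled = FeatureScaler().fit_transform(clinical)
    return ExpressionDataset(
        values=np.hstack([ds.values, scaled]),
        gene_ids=ds.gene_ids + [str(n) for n in feature_names],
        sample_ids=ds.sample_ids,
        labels=ds.labels,
        n_clinical=ds.n_clinical + clinical.shape[1],
    )


_STAGE_RE = re.compile(r"^\s*(?:stage\s*)?([IVX]+)\s*([A-Z0-9]*)\s*$", re.IGNORECASE)


def label_stage(stage_string: str) -> int:
    """Binary tumor-stage label: stage I (any sub-stage) -> 0, later -> 1.

    Case-insensitive; "Stage I", "stage ia", "IB" are early (0); "II", "III",
    "IV" and sub-stages are late (1). Missing or unparsable stages raise so
    the caller can exclude the sample.
    """
    if stage_string is None:
        raise ValueError("missing stage")
    m = _STAGE_RE.match(str(stage_string))
    if not m:
        raise ValueError(f"unrecognised stage {stage_string!r}")
    roman = m.group(1).upper()
    if roman == "I":
        return 0
    if roman in ("II", "III", "IV"):
        return 1
    raise ValueError(f"unrecognised stage numeral in {stage_string!r}")


def order_genes_by_groups(
    gene_ids: Sequence[str],
    grouping: Mapping[str, Sequence[str]],
) -> np.ndarray:
    """Permutation placing genes of the same group contiguously.

    ``grouping`` maps group name -> genes, iterated in insertion order. A gene
    in several groups is placed once, at its first group. Ungrouped genes are
    appended at the end in their original order. Always returns a valid
    permutation of ``range(len(gene_ids))``.
    """
    index: dict[str, list[int]] = {}
    for j, g in enumerate(gene_ids):
        index.setdefault(g, []).append(j)
    placed: set[int] = set()
    order: list[int] = []
    for genes in grouping.values():
        for g in genes:
            for j in index.get(g, ()):
                if j not in placed:
                    placed.add(j)
                    order.append(j)
    for j in range(len(gene_ids)):
        if j not in placed:
            order.append(j)
    return np.array(order, dtype=int)
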