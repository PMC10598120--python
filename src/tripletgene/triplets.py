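"""Balanced triplet construction, online categorization and strict semi-hard mining.

A triplet (anchor a, positive p, negative n) is categorized from the squared
distances dp2 = d(x_a, x_p) and dn2 = d(x_a, x_n) of the current embedding:

    hard       dn2 < dp2                (negative closer than positive)
    easy       dn2 - dp2 >= margin      (triplet loss exactly zero)
    semi-hard  0 <= dn2 - dp2 < margin

The category depends on which same-class member plays the anchor: switching
anchor and positive can turn a semi-hard triplet hard (or easy). The *strict*
semi-hard miner double-checks every semi-hard triplet in the switched
orientation and keeps only those that remain semi-hard both ways.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .losses import LossConfig, _pair_d2

__all__ = [
    "Triplet",
    "TripletSet",
    "TripletCategory",
    "CategoryCounts",
    "build_triplets",
    "categorize",
    "categorize_all",
    "semi_hard_filter",
    "strict_semi_hard_filter",
    "select_hard_supplement",
]


class TripletCategory(enum.Enum):
    EASY = "easy"
    SEMI_HARD = "semi_hard"
    HARD = "hard"


@dataclass(frozen=True)
class Triplet:
    """Index triple; the positive shares the anchor's class, the negative does not."""

    anchor: int
    positive: int
    negative: int


@dataclass
class TripletSet:
    """Parallel index arrays of anchors, positives and negatives.

    Balanced by construction: half the anchors come from each class (for even
    totals). Iterating yields :class:`Triplet` records.
    """

    anchors: np.ndarray
    positives: np.ndarray
    negatives: np.ndarray
    n_disease_anchors: int
    n_control_anchors: int
    seed: int

    def __post_init__(self) -> None:
        self.anchors = np.asarray(self.anchors, dtype=int)
        self.positives = np.asarray(self.positives, dtype=int)
        self.negatives = np.asarray(self.negatives, dtype=int)
        if not (len(self.anchors) == len(self.positives) == len(self.negatives)):
            raise ValueError("index arrays must have equal length")
        if np.any(self.anchors == self.positives):
            raise ValueError("anchor and positive must be distinct samples")

    def __len__(self) -> int:
        return len(self.anchors)

    def __getitem__(self, i: int) -> Triplet:
        return Triplet(int(self.anchors[i]), int(self.positives[i]), int(self.negatives[i]))

    def swapped(self) -> "TripletSet":
        """Every triplet with anchor and positive exchanged."""
        return TripletSet(
            self.positives.copy(),
            self.anchors.copy(),
            self.negatives.copy(),
            self.n_disease_anchors,
            self.n_control_anchors,
            self.seed,
        )

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {"anchor": self.anchors, "positive": self.positives, "negative": self.negatives}
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "TripletSet":
        df = pd.read_csv(path, sep="\t")
        a = df["anchor"].to_numpy()
        return cls(a, df["positive"].to_numpy(), df["negative"].to_numpy(), 0, 0, seed=-1)


@dataclass
class CategoryCounts:
    """Per-epoch triplet category tallies (the training-trajectory record)."""

    epoch: int
    easy: int
    semi_hard: int
    hard: int
    strict_semi_hard: int

    def __post_init__(self) -> None:
        if self.strict_semi_hard > self.semi_hard:
            raise ValueError("strict semi-hard count cannot exceed semi-hard count")

    @property
    def total(self) -> int:
        return self.easy + self.semi_hard + self.hard


def build_triplets(labels, n_triplets: int, seed: int) -> TripletSet:
    """Draw ``n_triplets`` random triplets with balanced anchor classes.

    Half the triplets take their anchor from class 1 (disease), half from
    class 0. Anchors and negatives are drawn uniformly with replacement;
    the positive is drawn uniformly from the anchor's class excluding the
    anchor itself. Reproducible from ``seed``.
    """
    labels = np.asarray(labels, dtype=int)
    if n_triplets % 2 != 0:
        raise ValueError("n_triplets must be even for balanced anchors")
    idx_by_class = {c: np.where(labels == c)[0] for c in (0, 1)}
    for c, idx in idx_by_class.items():
        if len(idx) < 2:
            raise ValueError(
                f"class {c} has {len(idx)} sample(s); cannot draw a positive "
                "distinct from the anchor"
            )
    rng = np.random.default_rng(seed)
    half = n_triplets // 2
    parts = []
    for cls, count in ((1, half), (0, half)):
        own = idx_by_class[cls]
        other = idx_by_class[1 - cls]
        m = len(own)
        a_pos = rng.integers(0, m, size=count)
        # uniform over the m-1 non-anchor members of the class
        p_pos = (a_pos + 1 + rng.integers(0, m - 1, size=count)) % m
        neg = other[rng.integers(0, len(other), size=count)]
        parts.append((own[a_pos], own[p_pos], neg))
    anchors = np.concatenate([p[0] for p in parts])
    positives = np.concatenate([p[1] for p in parts])
    negatives = np.concatenate([p[2] for p in parts])
    return TripletSet(anchors, positives, negatives, half, half, seed)


def categorize(dp2: float, dn2: float, m: float) -> TripletCategory:
    """Category from squared anchor-positive and anchor-negative distances.

    Ties: dn2 == dp2 is semi-hard (gap 0 < m); dn2 - dp2 == m is easy (the
    triplet loss is exactly zero there).
    """
    if dp2 < 0 or dn2 < 0 or m <= 0:
        raise ValueError("distances must be non-negative and margin positive")
    if dn2 < dp2:
        return TripletCategory.HARD
    if dn2 - dp2 >= m:
        return TripletCategory.EASY
    return TripletCategory.SEMI_HARD


_CAT_CODES = np.array([TripletCategory.HARD, TripletCategory.SEMI_HARD, TripletCategory.EASY])


def _category_codes(
    embeddings: np.ndarray,
    anchors: np.ndarray,
    positives: np.ndarray,
    negatives: np.ndarray,
    m: float,
    metric: str,
) -> np.ndarray:
    """0 = hard, 1 = semi-hard, 2 = easy, per triplet."""
    E = np.asarray(embeddings, dtype=float)
    n = E.shape[0]
    for arr in (anchors, positives, negatives):
        if np.any(arr < 0) or np.any(arr >= n):
            raise IndexError("triplet index out of range of the embedding matrix")
    dp2 = _pair_d2(E, anchors, positives, metric)
    dn2 = _pair_d2(E, anchors, negatives, metric)
    gap = dn2 - dp2
    codes = np.ones(len(anchors), dtype=int)  # semi-hard
    codes[gap < 0] = 0
    codes[gap >= m] = 2
    return codes


def categorize_all(
    embeddings: np.ndarray,
    ts: TripletSet,
    m: float,
    metric: str = "squared_euclidean",
    epoch: int = 0,
) -> tuple[list[TripletCategory], CategoryCounts]:
    """Categorize every triplet of the set under the current embedding.

    Also reports :class:`CategoryCounts` (including the strict semi-hard
    tally), whose easy + semi_hard + hard always equals ``len(ts)``.
    """
    codes = _category_codes(embeddings, ts.anchors, ts.positives, ts.negatives, m, metric)
    strict = strict_semi_hard_filter(embeddings, ts, m, metric)
    counts = CategoryCounts(
        epoch=epoch,
        easy=int((codes == 2).sum()),
        semi_hard=int((codes == 1).sum()),
        hard=int((codes == 0).sum()),
        strict_semi_hard=int(len(strict)),
    )
    return [_CAT_CODES[c] for c in codes], counts


def semi_hard_filter(
    embeddings: np.ndarray,
    ts: TripletSet,
    m: float,
    metric: str = "squared_euclidean",
) -> np.ndarray:
    """Indices of triplets semi-hard in the given orientation only.

    The conventional miner, used when the switching constraint is disabled.
    """
    codes = _category_codes(embeddings, ts.anchors, ts.positives, ts.negatives, m, metric)
    return np.where(codes == 1)[0]


def strict_semi_hard_filter(
    embeddings: np.ndarray,
    ts: TripletSet,
    m: float,
    metric: str = "squared_euclidean",
) -> np.ndarray:
    """Indices of triplets semi-hard in BOTH anchor orientations.

    A triplet is retained iff it is semi-hard as given and still semi-hard
    after switching anchor and positive (distances measured from the
    positive). The result is invariant under replacing (a, p, n) by (p, a, n).
    """
    fwd = _category_codes(embeddings, ts.anchors, ts.positives, ts.negatives, m, metric)
    swt = _category_codes(embeddings, ts.positives, ts.anchors, ts.negatives, m, metric)
    return np.where((fwd == 1) & (swt == 1))[0]


def select_hard_supplement(
    embeddings: np.ndarray,
    ts: TripletSet,
    m: float,
    k: int,
    loss_cfg: LossConfig | None = None,
) -> np.ndarray:
    """The k hard triplets of smallest triplet loss (ties by triplet index).

    Used by the optional hard-inclusion training mode that adds a capped
    number of the least-offending hard triplets to the retained set.
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    if loss_cfg is None:
        loss_cfg = LossConfig(margin=m)
    metric = loss_cfg.metric
    codes = _category_codes(embeddings, ts.anchors, ts.positives, ts.negatives, m, metric)
    hard_idx = np.where(codes == 0)[0]
    if k == 0 or len(hard_idx) == 0:
        return np.array([], dtype=int)
    E = np.asarray(embeddings, dtype=float)
    a, p, n = ts.anchors[hard_idx], ts.positives[hard_idx], ts.negatives[hard_idx]
    losses = np.maximum(
        _pair_d2(E, a, p, metric) - _pair_d2(E, a, n, metric) + loss_cfg.margin, 0.0
    )
    order = np.lexsort((hard_idx, losses))
    return np.sort(hard_idx[order[:k]])
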