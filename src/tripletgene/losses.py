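"""Triplet, switching, angular and joint losses with analytic gradients.

All hinge losses operate on *squared* distances, matching the display form

    l_triplet   = [ ||x_a - x_p||^2 - ||x_a - x_n||^2 + m ]+
    l_switching = [ ||x_a' - x_p'||^2 - ||x_a' - x_n||^2 + m ]+   (a' = p, p' = a)
    l_angular   = [ ||x_a - x_p||^2 - 4 tan^2(alpha) ||x_n - x_c||^2 ]+

with x_c = (x_a + x_p) / 2 and hinge [t]+ = max(t, 0). The squared-distance
convention keeps "zero triplet loss" exactly equivalent to the "easy"
category boundary used by the miner.

The cosine ablation replaces the squared Euclidean distance inside the
triplet and switching terms (and the categorizer) by the cosine distance
1 - cos; the angular term keeps its Euclidean triangle construction, which
is defined geometrically and has no cosine analogue.

Scalar entry points (:func:`triplet_loss` & co.) take an
:class:`EmbeddedTriplet`; training uses the vectorized
:func:`batch_loss` / :func:`batch_loss_grad` over an embedding matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "LossConfig",
    "EmbeddedTriplet",
    "distance2",
    "triplet_loss",
    "switching_loss",
    "angular_loss",
    "joint_loss",
    "batch_loss",
    "batch_loss_grad",
]

METRICS = ("squared_euclidean", "cosine")
ALPHA_GRID = (30.0, 45.0, 60.0, 75.0)


@dataclass
class LossConfig:
    """Margin, angular degree, distance metric and loss-term toggles.

    margin separates easy from semi-hard triplets and offsets the hinge;
    alpha (degrees) bounds the angle at the negative vertex of the
    (x_c, x_n) triangle. All three terms enabled is the full joint loss;
    subsets reproduce the ablation variants.
    """

    margin: float = 0.5
    alpha: float = 45.0
    metric: str = "squared_euclidean"
    use_triplet: bool = True
    use_switching: bool = True
    use_angular: bool = True

    def __post_init__(self) -> None:
        if not self.margin > 0:
            raise ValueError("margin must be positive")
        if not 0 < self.alpha < 90:
            raise ValueError("alpha must lie in (0, 90) degrees")
        if self.metric not in METRICS:
            raise ValueError(f"metric must be one of {METRICS}")
        if not (self.use_triplet or self.use_switching or self.use_angular):
            raise ValueError("at least one loss term must be enabled")

    @property
    def tan2_alpha(self) -> float:
        return math.tan(math.radians(self.alpha)) ** 2


@dataclass
class EmbeddedTriplet:
    """Embedded anchor, positive and negative vectors of equal dimension."""

    x_a: np.ndarray
    x_p: np.ndarray
    x_n: np.ndarray

    def __post_init__(self) -> None:
        self.x_a = np.asarray(self.x_a, dtype=float)
        self.x_p = np.asarray(self.x_p, dtype=float)
        self.x_n = np.asarray(self.x_n, dtype=float)
        if not (self.x_a.shape == self.x_p.shape == self.x_n.shape):
            raise ValueError("triplet vectors must share one dimension")
        if not all(np.all(np.isfinite(v)) for v in (self.x_a, self.x_p, self.x_n)):
            raise ValueError("triplet vectors must be finite")

    @property
    def center(self) -> np.ndarray:
        """Midpoint of anchor and positive (x_c)."""
        return 0.5 * (self.x_a + self.x_p)

    def swapped(self) -> "EmbeddedTriplet":
        """Anchor and positive exchanged (the switching condition)."""
        return EmbeddedTriplet(self.x_p, self.x_a, self.x_n)


def distance2(x: np.ndarray, y: np.ndarray, metric: str = "squared_euclidean") -> float:
    """Squared Euclidean distance, or cosine distance 1 - cos(x, y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must share one dimension")
    if metric == "squared_euclidean":
        d = x - y
        return float(d @ d)
    if metric == "cosine":
        nx, ny = np.linalg.norm(x), np.linalg.norm(y)
        if nx == 0 or ny == 0:
            raise ValueError("cosine distance undefined for a zero vector")
        return float(1.0 - (x @ y) / (nx * ny))
    raise ValueError(f"unknown metric {metric!r}")


def _hinge(t: float) -> float:
    return t if t > 0 else 0.0


def triplet_loss(t: EmbeddedTriplet, cfg: LossConfig) -> float:
    """[d(x_a, x_p) - d(x_a, x_n) + m]+ under cfg.metric."""
    dp = distance2(t.x_a, t.x_p, cfg.metric)
    dn = distance2(t.x_a, t.x_n, cfg.metric)
    return _hinge(dp - dn + cfg.margin)


def switching_loss(t: EmbeddedTriplet, cfg: LossConfig) -> float:
    """Triplet loss with anchor and positive roles exchanged."""
    return triplet_loss(t.swapped(), cfg)


def angular_loss(t: EmbeddedTriplet, cfg: LossConfig) -> float:
    """[||x_a - x_p||^2 - 4 tan^2(alpha) ||x_n - x_c||^2]+.

    Always squared Euclidean, regardless of ``cfg.metric``.
    """
    ap = t.x_a - t.x_p
    nc = t.x_n - t.center
    return _hinge(float(ap @ ap) - 4.0 * cfg.tan2_alpha * float(nc @ nc))


def joint_loss(t: EmbeddedTriplet, cfg: LossConfig) -> float:
    """Sum of the enabled terms (triplet + switching + angular = full loss)."""
    total = 0.0
    if cfg.use_triplet:
        total += triplet_loss(t, cfg)
    if cfg.use_switching:
        total += switching_loss(t, cfg)
    if cfg.use_angular:
        total += angular_loss(t, cfg)
    return total


# ---------------------------------------------------------------------------
# vectorized batch forms


def _pair_d2(E: np.ndarray, i: np.ndarray, j: np.ndarray, metric: str) -> np.ndarray:
    if metric == "squared_euclidean":
        d = E[i] - E[j]
        return np.einsum("ij,ij->i", d, d)
    norms = np.linalg.norm(E, axis=1)
    if np.any(norms[i] == 0) or np.any(norms[j] == 0):
        raise ValueError("cosine distance undefined for a zero vector")
    cos = np.einsum("ij,ij->i", E[i], E[j]) / (norms[i] * norms[j])
    return 1.0 - cos


def _batch_terms(
    E: np.ndarray, a: np.ndarray, p: np.ndarray, n: np.ndarray, cfg: LossConfig
) -> dict[str, np.ndarray]:
    """Pre-hinge values of every enabled term, per triplet."""
    out: dict[str, np.ndarray] = {}
    if cfg.use_triplet or cfg.use_switching:
        dp = _pair_d2(E, a, p, cfg.metric)
        if cfg.use_triplet:
            out["triplet"] = dp - _pair_d2(E, a, n, cfg.metric) + cfg.margin
        if cfg.use_switching:
            out["switching"] = dp - _pair_d2(E, p, n, cfg.metric) + cfg.margin
    if cfg.use_angular:
        ap = E[a] - E[p]
        nc = E[n] - 0.5 * (E[a] + E[p])
        out["angular"] = np.einsum("ij,ij->i", ap, ap) - 4.0 * cfg.tan2_alpha * np.einsum(
            "ij,ij->i", nc, nc
        )
    return out


def per_triplet_losses(
    E: np.ndarray, a: np.ndarray, p: np.ndarray, n: np.ndarray, cfg: LossConfig
) -> np.ndarray:
    """Joint loss of every (a, p, n) triplet under embedding rows ``E``."""
    terms = _batch_terms(E, np.asarray(a), np.asarray(p), np.asarray(n), cfg)
    return sum(np.maximum(v, 0.0) for v in terms.values())


def batch_loss(
    embeddings: np.ndarray,
    triplet_indices,
    ts,
    cfg: LossConfig,
) -> float:
    """Mean joint loss over the listed triplets of a triplet set."""
    idx = np.asarray(triplet_indices, dtype=int)
    if idx.size == 0:
        raise ValueError("empty batch")
    a, p, n = ts.anchors[idx], ts.positives[idx], ts.negatives[idx]
    return float(per_triplet_losses(np.asarray(embeddings, float), a, p, n, cfg).mean())


def batch_loss_grad(
    embeddings: np.ndarray,
    triplet_indices,
    ts,
    cfg: LossConfig,
) -> tuple[float, np.ndarray]:
    """Mean joint loss and its gradient with respect to the embedding rows.

    The gradient accumulates contributions from every active (positive-hinge)
    term into the rows indexed by the batch's anchors, positives and
    negatives; rows of samples outside the batch receive zero.
    """
    E = np.asarray(embeddings, dtype=float)
    idx = np.asarray(triplet_indices, dtype=int)
    if idx.size == 0:
        raise ValueError("empty batch")
    a, p, n = ts.anchors[idx], ts.positives[idx], ts.negatives[idx]
    B = idx.size
    terms = _batch_terms(E, a, p, n, cfg)
    loss = float(sum(np.maximum(v, 0.0) for v in terms.values()).mean())

    grad = np.zeros_like(E)
    w = 1.0 / B  # mean reduction

    def _cos_pair_grads(i, j, active):
        # d(1 - cos)/dE[i], d/dE[j] for active triplets
        Ei, Ej = E[i[active]], E[j[active]]
        ni = np.linalg.norm(Ei, axis=1, keepdims=True)
        nj = np.linalg.norm(Ej, axis=1, keepdims=True)
        cos = np.einsum("ij,ij->i", Ei, Ej)[:, None] / (ni * nj)
        gi = cos * Ei / ni**2 - Ej / (ni * nj)
        gj = cos * Ej / nj**2 - Ei / (ni * nj)
        return gi, gj

    def _add_hinged_pair(i, j, sign, active):
        # sign * d(d2(i,j)) for active triplets, scaled by w
        if cfg.metric == "squared_euclidean":
            g = 2.0 * (E[i[active]] - E[j[active]])
            np.add.at(grad, i[active], sign * w * g)
            np.add.at(grad, j[active], -sign * w * g)
        else:
            gi, gj = _cos_pair_grads(i, j, active)
            np.add.at(grad, i[active], sign * w * gi)
            np.add.at(grad, j[active], sign * w * gj)

    if "triplet" in terms:
        act = terms["triplet"] > 0
        if np.any(act):
            _add_hinged_pair(a, p, +1.0, act)
            _add_hinged_pair(a, n, -1.0, act)
    if "switching" in terms:
        act = terms["switching"] > 0
        if np.any(act):
            _add_hinged_pair(a, p, +1.0, act)  # d(a,p) symmetric in its arguments
            _add_hinged_pair(p, n, -1.0, act)
    if "angular" in terms:
        act = terms["angular"] > 0
        if np.any(act):
            t2 = cfg.tan2_alpha
            ap = E[a[act]] - E[p[act]]
            nc = E[n[act]] - 0.5 * (E[a[act]] + E[p[act]])
            np.add.at(grad, a[act], w * (2.0 * ap + 4.0 * t2 * nc))
            np.add.at(grad, p[act], w * (-2.0 * ap + 4.0 * t2 * nc))
            np.add.at(grad, n[act], w * (-8.0 * t2 * nc))
    return loss, grad
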