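"""Minimal NumPy neural-network kernels: non-overlapping 1D conv, ReLU,
ceil-mode max pooling, fully connected layers, Xavier init and Adam.

Because the convolution stride equals the window length, the conv layer is
exactly a per-window linear map: reshaping the input to
``(batch, n_windows, window)`` and multiplying by a ``(window, n_filters)``
kernel. That makes forward and backward passes plain matrix algebra.
"""

from __future__ import annotations

import numpy as np

__all__ = ["xavier_uniform", "Adam", "relu", "Conv1DEmbedder"]


def xavier_uniform(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


class Adam:
    """Adam optimizer over a dict of named parameter arrays."""

    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            self.params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class Conv1DEmbedder:
    """conv(window, stride=window) -> ReLU -> max pool -> flatten -> FC.

    Optionally L2-normalizes the output rows so embeddings live on the unit
    sphere, which fixes the scale that a constant triplet margin acts on.
    Pooling is ceil-mode: a trailing partial pool window is kept, so a conv
    output of length 1 survives any pool size.
    """

    def __init__(self, window: int, n_windows: int, n_filters: int,
                 pool_size: int, embedding_dim: int, init_seed: int,
                 normalize: bool = True):
        if window < 1 or n_windows < 1:
            raise ValueError("need at least one window of length >= 1")
        self.window = window
        self.n_windows = n_windows
        self.n_filters = n_filters
        self.pool_size = pool_size
        self.embedding_dim = embedding_dim
        self.normalize = normalize
        self.n_pooled = -(-n_windows // pool_size)  # ceil
        self.flat_dim = self.n_pooled * n_filters
        rng = np.random.default_rng(init_seed)
        self.params: dict[str, np.ndarray] = {
            "Wc": xavier_uniform(rng, window, n_filters, (window, n_filters)),
            "bc": np.zeros(n_filters),
            "Wf": xavier_uniform(rng, self.flat_dim, embedding_dim,
                                 (self.flat_dim, embedding_dim)),
            "bf": np.zeros(embedding_dim),
        }

    # -- forward -----------------------------------------------------------
    def forward(self, X: np.ndarray, cache: dict | None = None) -> np.ndarray:
        """Embed a (batch, n_windows * window) matrix; rows are samples."""
        X = np.asarray(X, dtype=float)
        B = X.shape[0]
        Xw = X.reshape(B, self.n_windows, self.window)
        Z = Xw @ self.params["Wc"] + self.params["bc"]  # (B, nw, F)
        A = relu(Z)
        pad = self.n_pooled * self.pool_size - self.n_windows
        if pad:
            A_p = np.concatenate(
                [A, np.full((B, pad, self.n_filters), -np.inf)], axis=1
            )
        else:
            A_p = A
        A_p = A_p.reshape(B, self.n_pooled, self.pool_size, self.n_filters)
        arg = A_p.argmax(axis=2)
        P = np.take_along_axis(A_p, arg[:, :, None, :], axis=2)[:, :, 0, :]
        F = P.reshape(B, self.flat_dim)
        E_raw = F @ self.params["Wf"] + self.params["bf"]
        if self.normalize:
            norms = np.maximum(np.linalg.norm(E_raw, axis=1, keepdims=True), 1e-12)
            E = E_raw / norms
        else:
            norms = None
            E = E_raw
        if cache is not None:
            cache.update(Xw=Xw, Z=Z, arg=arg, F=F, E_raw=E_raw, norms=norms, E=E)
        return E

    # -- backward ----------------------------------------------------------
    def backward(self, cache: dict, dE: np.ndarray) -> dict[str, np.ndarray]:
        """Parameter gradients from upstream dLoss/dEmbedding."""
        B = dE.shape[0]
        if self.normalize:
            norms, E = cache["norms"], cache["E"]
            dot = np.einsum("ij,ij->i", E, dE)[:, None]
            dEr = (dE - E * dot) / norms
        else:
            dEr = dE
        grads = {
            "Wf": cache["F"].T @ dEr,
            "bf": dEr.sum(axis=0),
        }
        dF = dEr @ self.params["Wf"].T
        dP = dF.reshape(B, self.n_pooled, self.n_filters)
        # route pooled gradients back to argmax positions
        dA = np.zeros((B, self.n_windows, self.n_filters))
        # every pool group holds >= 1 real window, so argmax never lands on padding
        win_idx = cache["arg"] + (np.arange(self.n_pooled) * self.pool_size)[None, :, None]
        b_idx = np.arange(B)[:, None, None]
        f_idx = np.arange(self.n_filters)[None, None, :]
        np.add.at(dA, (b_idx, win_idx, f_idx), dP)
        dZ = dA * (cache["Z"] > 0)
        grads["Wc"] = np.einsum("bwk,bwf->kf", cache["Xw"], dZ)
        grads["bc"] = dZ.sum(axis=(0, 1))
        return grads

    # -- persistence -------------------------------------------------------
    def copy_params(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_params(self, params: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = params[k].copy()


class LinearSigmoid:
    """One fully connected layer to a single score, squashed by a sigmoid."""

    def __init__(self, input_dim: int, init_seed: int = 0):
        rng = np.random.default_rng(init_seed)
        self.params = {
            "w": xavier_uniform(rng, input_dim, 1, (input_dim,)),
            "b": np.zeros(1),
        }

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        z = np.asarray(X, float) @ self.params["w"] + self.params["b"][0]
        return 1.0 / (1.0 + np.exp(-z))

    def bce_grad(self, X: np.ndarray, y: np.ndarray) -> tuple[float, dict[str, np.ndarray]]:
        X = np.asarray(X, float)
        y = np.asarray(y, float)
        p = self.predict_proba(X)
        eps = 1e-12
        loss = float(-np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))
        dz = (p - y) / len(y)
        return loss, {"w": X.T @ dz, "b": np.array([dz.sum()])}
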