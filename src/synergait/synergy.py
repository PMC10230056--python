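"""Muscle-synergy extraction by non-negative matrix factorization.

The envelope matrix of one analysis window, E (p muscles x n time points),
is factored as E ~ W H with W (p x k) the nonnegative synergy weights and
H (k x n) the activation coefficients, by classic multiplicative updates
minimizing the Frobenius residual ||E - W H||_F.  Random restarts guard
against local minima; the restart with the smallest residual wins.  Synergy
weights are normalized to the maximum weight within each synergy (H is
rescaled inversely so the product is unchanged), and the flattened weight
vector of a k=1 factorization is the 4-dimensional MS feature of a window.

The per-window extractor runs the multiplicative updates vectorized over
all windows at once; results are identical to calling :func:`nnmf` window
by window with the same derived seeds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "SynergyModel",
    "minmax_normalize",
    "nnmf",
    "normalize_weights",
    "MuscleSynergyFeatures",
    "ms_features",
]

_DELTA = 1e-12  # multiplicative-update denominator stabilizer


@dataclass
class SynergyModel:
    """Result of one NNMF factorization (the best restart)."""

    W: np.ndarray          # (p, k), nonnegative
    H: np.ndarray          # (k, n), nonnegative
    residual: float        # ||E - W H||_F at convergence
    n_iter: int
    restart_index: int

    def reconstruct(self) -> np.ndarray:
        return self.W @ self.H


def minmax_normalize(window: np.ndarray, per_channel: bool = True) -> np.ndarray:
    """Map each channel of a window into [0, 1]; constant channels map to 0."""
    x = np.asarray(window, dtype=float)
    if per_channel:
        lo = x.min(axis=-1, keepdims=True)
        hi = x.max(axis=-1, keepdims=True)
    else:
        lo = x.min(axis=(-2, -1), keepdims=True)
        hi = x.max(axis=(-2, -1), keepdims=True)
    span = hi - lo
    out = np.zeros_like(x)
    np.divide(x - lo, span, out=out, where=span > 0)
    return out


def _mu_batch(
    E: np.ndarray,
    W: np.ndarray,
    H: np.ndarray,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Batched multiplicative updates on a stack of problems.

    E: (B, p, n); W: (B, p, k); H: (B, k, n).  Each problem iterates until
    its own relative residual change drops below ``tol`` or ``max_iter``.
    Returns (W, H, residuals, n_iters).
    """
    B = E.shape[0]
    res = np.linalg.norm(E - W @ H, axis=(1, 2))
    n_iter = np.zeros(B, dtype=np.int64)
    active = np.arange(B)
    for _ in range(max_iter):
        if active.size == 0:
            break
        Ea, Wa, Ha = E[active], W[active], H[active]
        WT = Wa.transpose(0, 2, 1)
        Ha = Ha * (WT @ Ea) / (WT @ Wa @ Ha + _DELTA)
        HT = Ha.transpose(0, 2, 1)
        Wa = Wa * (Ea @ HT) / (Wa @ (Ha @ HT) + _DELTA)
        new_res = np.linalg.norm(Ea - Wa @ Ha, axis=(1, 2))
        W[active], H[active] = Wa, Ha
        n_iter[active] += 1
        prev = res[active]
        res[active] = new_res
        rel = np.abs(prev - new_res) / np.maximum(prev, _DELTA)
        active = active[rel >= tol]
    return W, H, res, n_iter


def _nnmf_batch(
    E: np.ndarray,
    k: int,
    n_restarts: int,
    max_iter: int,
    tol: float,
    rngs: list[np.random.Generator],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Best-of-restarts NNMF on a stack of (p, n) problems.

    ``rngs[b]`` supplies restart initializations for problem b sequentially
    (restart r is the r-th (W, H) draw), so results are independent of the
    batch composition.
    """
    B, p, n = E.shape
    best_W = np.zeros((B, p, k))
    best_H = np.zeros((B, k, n))
    best_res = np.full(B, np.inf)
    best_iter = np.zeros(B, dtype=np.int64)
    best_restart = np.zeros(B, dtype=np.int64)
    for r in range(n_restarts):
        W = np.empty((B, p, k))
        H = np.empty((B, k, n))
        for b, rng in enumerate(rngs):
            W[b] = 1.0 - rng.random((p, k))  # uniform on (0, 1]
            H[b] = 1.0 - rng.random((k, n))
        W, H, res, it = _mu_batch(E, W, H, max_iter, tol)
        better = res < best_res
        best_W[better], best_H[better] = W[better], H[better]
        best_res[better] = res[better]
        best_iter[better] = it[better]
        best_restart[better] = r
    return best_W, best_H, best_res, best_iter, best_restart


def nnmf(
    E: np.ndarray,
    k: int,
    n_restarts: int = 20,
    max_iter: int = 500,
    tol: float = 1e-6,
    seed=None,
) -> SynergyModel:
    """Factor a nonnegative matrix E (p x n) into W H with k synergies.

    Multiplicative updates from uniform (0, 1] random initializations, one
    per restart, all drawn sequentially from a generator seeded by ``seed``;
    the restart with the smallest Frobenius residual is returned.  Within a
    restart the residual is non-increasing.
    """
    E = np.asarray(E, dtype=float)
    if E.ndim != 2:
        raise ValueError("E must be a 2-D matrix")
    if np.any(E < 0):
        raise ValueError("E must be nonnegative")
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > min(E.shape):
        raise ValueError(f"k={k} exceeds min(p, n)={min(E.shape)}")
    rng = np.random.default_rng(seed)
    W, H, res, it, restart = _nnmf_batch(
        E[np.newaxis], k, n_restarts, max_iter, tol, [rng]
    )
    return SynergyModel(
        W=W[0], H=H[0], residual=float(res[0]), n_iter=int(it[0]),
        restart_index=int(restart[0]),
    )


def normalize_weights(model: SynergyModel) -> SynergyModel:
    """Scale each synergy's weights to max 1 (H rescaled so W H is unchanged)."""
    W = model.W.copy()
    H = model.H.copy()
    scale = W.max(axis=0)
    zero = scale <= 0
    if np.any(zero):
        warnings.warn("all-zero synergy column left unnormalized")
    safe = np.where(zero, 1.0, scale)
    W /= safe
    H *= safe[:, np.newaxis]
    return SynergyModel(W=W, H=H, residual=model.residual, n_iter=model.n_iter,
                        restart_index=model.restart_index)


def _order_columns(W: np.ndarray, H: np.ndarray) -> np.ndarray:
    """Deterministic synergy ordering (k > 1): by dominant-muscle index,
    ties by descending activation energy.  Resolves the column-permutation
    ambiguity of NMF so features are comparable across windows."""
    k = W.shape[1]
    energy = (H**2).sum(axis=1)
    order = sorted(range(k), key=lambda j: (int(np.argmax(W[:, j])), -energy[j]))
    return np.asarray(order)


class MuscleSynergyFeatures(BaseEstimator, TransformerMixin):
    """MS feature bank: per-window synergy weights from a k-synergy NNMF.

    Each window (muscles x L) is min-max normalized over the whole window
    (jointly across channels, preserving the muscles' relative amplitudes
    that the synergy weights are meant to encode; set
    ``per_channel_norm=True`` to rescale each channel separately), factored
    with ``n_restarts`` multiplicative-update restarts, max-normalized, and
    its weight matrix flattened column-major into a muscles*k vector (4
    values for 4 muscles, k=1).  Restart initializations for window i are
    drawn from a generator seeded by (random_state, i), so the feature of a
    window does not depend on which other windows are in the batch.
    """

    def __init__(self, k: int = 1, n_restarts: int = 20, max_iter: int = 500,
                 tol: float = 1e-6, random_state: int = 0, per_channel_norm: bool = False):
        self.k = k
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state
        self.per_channel_norm = per_channel_norm

    def fit(self, X, y=None):
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[np.newaxis]
        B, p, L = X.shape
        if self.k > min(p, L):
            raise ValueError(f"k={self.k} exceeds min(muscles, window_len)")
        E = minmax_normalize(X, per_channel=self.per_channel_norm)
        zero_windows = ~np.any(E > 0, axis=(1, 2))
        if np.any(zero_windows):
            warnings.warn(f"{int(zero_windows.sum())} all-zero window(s); zero MS features")
        rngs = [np.random.default_rng([self.random_state, i]) for i in range(B)]
        W, H, _, _, _ = _nnmf_batch(E, self.k, self.n_restarts, self.max_iter,
                                    self.tol, rngs)
        out = np.empty((B, p * self.k))
        for b in range(B):
            scale = W[b].max(axis=0)
            Wn = W[b] / np.where(scale > 0, scale, 1.0)
            if self.k > 1:
                Hn = H[b] * np.where(scale > 0, scale, 1.0)[:, np.newaxis]
                Wn = Wn[:, _order_columns(Wn, Hn)]
            out[b] = Wn.ravel(order="F")
        out[zero_windows] = 0.0
        return out


def ms_features(windows, k: int = 1, n_restarts: int = 20, max_iter: int = 500,
                tol: float = 1e-6, seed: int = 0) -> np.ndarray:
    """MS features for a window set or (B, muscles, L) tensor."""
    data = windows.data if hasattr(windows, "data") else windows
    if hasattr(windows, "n_windows") and windows.n_windows == 0:
        raise ValueError("empty window set")
    return MuscleSynergyFeatures(
        k=k, n_restarts=n_restarts, max_iter=max_iter, tol=tol, random_state=seed
    ).transform(data)
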