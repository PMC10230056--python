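"""SMOTE oversampling of minority gait phases.

Classic SMOTE: each synthetic minority point is x + u (x_nn - x) with x a
uniformly chosen minority sample, x_nn one of its k nearest same-class
neighbours (Euclidean) and u ~ Uniform(0, 1), so every synthetic point lies
on the segment between its two parents.  Every minority class is raised to
the majority count; originals are preserved and ordered first.

Applied to training folds only — oversampling before a train/test split
leaks synthetic copies of test-adjacent points into training.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.neighbors import NearestNeighbors

__all__ = ["ResampleReport", "Smote", "smote"]


@dataclass
class ResampleReport:
    class_counts_before: dict = field(default_factory=dict)
    class_counts_after: dict = field(default_factory=dict)
    n_synthetic: int = 0
    k_neighbors: int = 5
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "class_counts_before": {str(k): int(v) for k, v in self.class_counts_before.items()},
            "class_counts_after": {str(k): int(v) for k, v in self.class_counts_after.items()},
            "n_synthetic": int(self.n_synthetic),
            "k_neighbors": int(self.k_neighbors),
            "seed": self.seed,
        }


class Smote(BaseEstimator):
    """Minority-class oversampler with the imblearn-style ``fit_resample``."""

    def __init__(self, k_neighbors: int = 5, random_state: int | None = None):
        self.k_neighbors = k_neighbors
        self.random_state = random_state

    def fit_resample(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[1] < 1:
            raise ValueError("X must be 2-D with at least one feature")
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y length mismatch")
        classes, counts = np.unique(y, return_counts=True)
        before = dict(zip(classes.tolist(), counts.tolist()))
        if len(classes) < 2:
            warnings.warn("single class present; nothing to balance")
            self.report_ = ResampleReport(before, dict(before), 0, self.k_neighbors,
                                          self.random_state)
            return X, y
        target = counts.max()
        rng = np.random.default_rng(self.random_state)
        X_new, y_new = [X], [y]
        n_syn_total = 0
        for cls, cnt in zip(classes, counts):
            need = int(target - cnt)
            if need == 0:
                continue
            if cnt <= self.k_neighbors:
                raise ValueError(
                    f"class {cls!r} has {cnt} samples, need > k_neighbors="
                    f"{self.k_neighbors}; use a smaller k"
                )
            Xc = X[y == cls]
            nn = NearestNeighbors(n_neighbors=self.k_neighbors + 1).fit(Xc)
            _, idx = nn.kneighbors(Xc)
            neighbors = idx[:, 1:]  # drop self
            base = rng.integers(0, cnt, size=need)
            pick = rng.integers(0, self.k_neighbors, size=need)
            u = rng.random(need)
            x0 = Xc[base]
            x1 = Xc[neighbors[base, pick]]
            X_new.append(x0 + u[:, np.newaxis] * (x1 - x0))
            y_new.append(np.full(need, cls, dtype=y.dtype))
            n_syn_total += need
        Xr = np.concatenate(X_new, axis=0)
        yr = np.concatenate(y_new, axis=0)
        after_classes, after_counts = np.unique(yr, return_counts=True)
        self.report_ = ResampleReport(
            class_counts_before=before,
            class_counts_after=dict(zip(after_classes.tolist(), after_counts.tolist())),
            n_synthetic=n_syn_total,
            k_neighbors=self.k_neighbors,
            seed=self.random_state,
        )
        return Xr, yr


def smote(X, y, k_neighbors: int = 5, seed: int | None = None):
    """Functional wrapper: returns (X_resampled, y_resampled, ResampleReport)."""
    s = Smote(k_neighbors=k_neighbors, random_state=seed)
    Xr, yr = s.fit_resample(X, y)
    return Xr, yr, s.report_
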