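"""Classifier harness: seeded random search, early-stopped NN training,
time-blocked 10-fold cross-validation, and the window-length study.

Folds are contiguous time blocks, not shuffled windows: sliding windows
overlap heavily, so shuffled CV would leak near-duplicate windows between
train and test.  Within each training portion the final contiguous
``val_frac`` block is the validation split used for hyperparameter scoring
and NN early stopping; SMOTE, when enabled, is applied to the training
block only.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .balance import Smote

__all__ = ["ClassifierSpec", "CVResult", "train_classifier", "crossvalidate",
           "window_length_study"]

CLASSIFIER_KINDS = ("DT", "KNN", "SVM", "NN")

# default hyperparameter search spaces, sampled log-uniform where noted
DEFAULT_SPACES = {
    "DT": {"max_depth": ("int", 2, 30)},
    "KNN": {"n_neighbors": ("int", 1, 25)},
    "SVM": {"C": ("log", 1.0, 1e2), "gamma": ("log", 3e-2, 3.0)},
    "NN": {"hidden_units": ("int", 16, 256), "learning_rate_init": ("log", 1e-4, 1e-2)},
}


@dataclass
class ClassifierSpec:
    kind: str = "SVM"
    space: dict = field(default_factory=dict)
    search_budget: int = 20
    seed: int = 0
    nn_max_epochs: int = 200
    nn_patience: int = 10

    def __post_init__(self) -> None:
        if self.kind not in CLASSIFIER_KINDS:
            raise ValueError(f"kind must be one of {CLASSIFIER_KINDS}")
        if not self.space:
            self.space = dict(DEFAULT_SPACES[self.kind])

    def sample_params(self, rng: np.random.Generator) -> dict:
        params = {}
        for name, (dist, lo, hi) in self.space.items():
            if dist == "int":
                params[name] = int(rng.integers(lo, hi + 1))
            elif dist == "log":
                params[name] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            else:
                raise ValueError(f"unknown distribution {dist!r}")
        return params


def _build(kind: str, params: dict, seed: int):
    if kind == "DT":
        return DecisionTreeClassifier(max_depth=params["max_depth"], random_state=seed)
    if kind == "KNN":
        return KNeighborsClassifier(n_neighbors=params["n_neighbors"])
    if kind == "SVM":
        return SVC(kernel="rbf", C=params["C"], gamma=params["gamma"],
                   cache_size=500, random_state=seed)
    if kind == "NN":
        return MLPClassifier(
            hidden_layer_sizes=(params["hidden_units"],),
            learning_rate_init=params["learning_rate_init"],
            random_state=seed,
        )
    raise ValueError(kind)


def _fit_nn_early_stopping(model: MLPClassifier, X, y, X_val, y_val,
                           max_epochs: int, patience: int):
    """Epoch-wise NN training, stopping after ``patience`` consecutive
    epochs without strict improvement of validation accuracy; the model
    state of the best epoch is returned."""
    classes = np.unique(np.concatenate([y, y_val]))
    best_acc = -np.inf
    best_model = None
    stall = 0
    epochs = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # per-epoch convergence warnings
        for _ in range(max_epochs):
            model.partial_fit(X, y, classes=classes)
            epochs += 1
            acc = model.score(X_val, y_val)
            if acc > best_acc:
                best_acc = acc
                best_model = copy.deepcopy(model)
                stall = 0
            else:
                stall += 1
                if stall >= patience:
                    break
    best_model.early_stop_epochs_ = epochs
    return best_model, best_acc


def train_classifier(X, y, spec: ClassifierSpec, X_val, y_val):
    """Seeded random hyperparameter search scored on the validation split.

    Returns (fitted_model, chosen_params, validation_accuracy).  Features
    are standardized on the training split (the scaler rides inside the
    returned pipeline).  NN models are trained epoch-wise with early
    stopping (patience ``nn_patience``); the other kinds fit in one shot.
    """
    X, y = np.asarray(X), np.asarray(y)
    X_val, y_val = np.asarray(X_val), np.asarray(y_val)
    if len(X_val) == 0:
        raise ValueError("validation split is empty")
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain at least two classes")
    scaler = StandardScaler().fit(X)
    Xs, Xs_val = scaler.transform(X), scaler.transform(X_val)
    rng = np.random.default_rng(spec.seed)
    best = (None, None, -np.inf)
    for trial in range(spec.search_budget):
        params = spec.sample_params(rng)
        model = _build(spec.kind, params, spec.seed)
        if spec.kind == "NN":
            model, acc = _fit_nn_early_stopping(
                model, Xs, y, Xs_val, y_val, spec.nn_max_epochs, spec.nn_patience
            )
        else:
            model.fit(Xs, y)
            acc = model.score(Xs_val, y_val)
        if acc > best[2]:
            best = (model, params, acc)
    model, params, acc = best
    return Pipeline([("scale", scaler), ("clf", model)]), params, acc


@dataclass
class CVResult:
    fold_accuracies: np.ndarray
    predictions: np.ndarray        # per-window predicted label over all folds
    fold_params: list
    scheme: str = ""
    feature_kind: str = ""
    fold_indices: list = field(default_factory=list)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def sd_accuracy(self) -> float:
        return float(np.std(self.fold_accuracies, ddof=1)) if len(self.fold_accuracies) > 1 else 0.0


def crossvalidate(
    X,
    y,
    spec: ClassifierSpec,
    folds: int = 10,
    val_frac: float = 0.1,
    balance: bool = True,
    k_neighbors: int = 5,
    scheme: str = "",
    feature_kind: str = "",
) -> CVResult:
    """Time-blocked k-fold CV; rows of X must be in window time order.

    Each fold's test set is one contiguous block (a distinct time segment);
    the rest trains, with its own trailing contiguous block as validation.
    Per-fold accuracy is the fraction of test windows labeled correctly.
    """
    X, y = np.asarray(X), np.asarray(y)
    n = len(X)
    if n < folds or folds < 2:
        raise ValueError(f"need at least {max(folds, 2)} windows for {folds} folds")
    blocks = np.array_split(np.arange(n), folds)
    accs, params_list, fold_idx = [], [], []
    predictions = np.full(n, -1, dtype=y.dtype)
    for f in range(folds):
        test_idx = blocks[f]
        train_idx = np.concatenate([blocks[g] for g in range(folds) if g != f])
        n_val = max(1, int(round(val_frac * len(train_idx))))
        fit_idx, val_idx = train_idx[:-n_val], train_idx[-n_val:]
        X_fit, y_fit = X[fit_idx], y[fit_idx]
        if len(np.unique(y_fit)) < 2:
            warnings.warn(f"fold {f}: single-class training data; skipped")
            continue
        if balance:
            X_fit, y_fit = Smote(k_neighbors=k_neighbors,
                                 random_state=spec.seed + f).fit_resample(X_fit, y_fit)
        model, params, _ = train_classifier(X_fit, y_fit, spec, X[val_idx], y[val_idx])
        pred = model.predict(X[test_idx])
        predictions[test_idx] = pred
        accs.append(float(np.mean(pred == y[test_idx])))
        params_list.append(params)
        fold_idx.append(test_idx)
    return CVResult(
        fold_accuracies=np.asarray(accs),
        predictions=predictions,
        fold_params=params_list,
        scheme=scheme,
        feature_kind=feature_kind,
        fold_indices=fold_idx,
    )


def window_length_study(
    feature_sets: dict,
    labels: dict,
    subject_ids: list,
    lengths_ms: tuple = (100, 200, 400, 600),
    kinds: tuple = CLASSIFIER_KINDS,
    search_budget: int = 5,
    val_frac: float = 0.1,
    seed: int = 0,
):
    """Subject-wise window-length x classifier accuracy grid.

    ``feature_sets[length_ms][subject]`` is that subject's feature matrix at
    one window length and ``labels[length_ms][subject]`` its labels.  The
    subjects are split into fourfold groups (6 train / 2 test); the grid
    holds the mean test accuracy per (length, classifier), and the argmax
    cell is returned alongside.
    """
    n_subj = len(subject_ids)
    if n_subj % 4 != 0:
        raise ValueError("subject count must be divisible by 4 for fourfold evaluation")
    pair = n_subj // 4
    test_groups = [subject_ids[i * pair : (i + 1) * pair] for i in range(4)]
    grid = np.zeros((len(lengths_ms), len(kinds)))
    for li, length in enumerate(lengths_ms):
        for ci, kind in enumerate(kinds):
            spec = ClassifierSpec(kind=kind, search_budget=search_budget, seed=seed)
            fold_accs = []
            for tg in test_groups:
                tr = [s for s in subject_ids if s not in tg]
                X_tr = np.concatenate([feature_sets[length][s] for s in tr])
                y_tr = np.concatenate([labels[length][s] for s in tr])
                X_te = np.concatenate([feature_sets[length][s] for s in tg])
                y_te = np.concatenate([labels[length][s] for s in tg])
                n_val = max(1, int(round(val_frac * len(X_tr))))
                model, _, _ = train_classifier(
                    X_tr[:-n_val], y_tr[:-n_val], spec, X_tr[-n_val:], y_tr[-n_val:]
                )
                fold_accs.append(model.score(X_te, y_te))
            grid[li, ci] = float(np.mean(fold_accs))
    best = np.unravel_index(np.argmax(grid), grid.shape)
    return grid, (lengths_ms[best[0]], kinds[best[1]])
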