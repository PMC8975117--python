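"""Classifiers and the continuous neural scorer, under LOSO validation.

Four models estimate the Leg Agility score from the feature vector:

* linear one-vs-one SVM (box constraint 36),
* kNN (k = 5, Euclidean, equal weights),
* decision tree (Gini-Simpson split criterion, at most 4 splits),
* a small neural network — two hidden layers of 16 tanh units and a linear
  scalar output — trained as a regressor on the un-rounded mean rater
  score, which gives a *continuous* severity estimate finer than the
  integer clinical scale.  Its discrete label is the clipped rounded score.

Validation is leave-one-subject-out (LOSO): each fold holds out every
recording of one subject, so a model is never tested on a leg of a subject
it has seen.  Features are z-scored per fold using training statistics only.

The neural scorer is trained by full-batch gradient descent on mean squared
error with an adaptive learning rate: after an epoch that reduces the loss
the rate grows by 10%; after a worsening epoch the step is reverted and the
rate shrinks by 20%.  Training stops at 2000 iterations or when the
gradient norm falls below 1e-5.
"""

from __future__ import annotations

import logging
import pickle
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from ._utils import round_half_away
from .errors import SchemaError, TrainingError, ValidationError
from .sensor_io import CohortManifest

logger = logging.getLogger(__name__)

ARTIFACT_VERSION = 1


@dataclass
class ModelSpec:
    """A model kind plus its hyperparameters (defaults = shipped values)."""

    kind: str  # svm | knn | dt | ann
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in DEFAULT_HYPERPARAMETERS:
            raise ValueError(f"unknown model kind {self.kind!r}")
        merged = dict(DEFAULT_HYPERPARAMETERS[self.kind])
        merged.update(self.hyperparameters)
        self.hyperparameters = merged


DEFAULT_HYPERPARAMETERS = {
    "svm": {"kernel": "linear", "box_constraint": 36.0},
    "knn": {"n_neighbors": 5, "metric": "euclidean", "weights": "uniform"},
    "dt": {"criterion": "gini", "max_splits": 4},
    "ann": {"hidden_layers": 2, "hidden_units": 16, "activation": "tanh"},
}


@dataclass
class TrainConfig:
    """Stop conditions and adaptive-learning-rate schedule for the scorer."""

    max_iterations: int = 2000
    gradient_floor: float = 1e-5
    initial_learning_rate: float = 0.01
    lr_increase: float = 1.10   # multiplier after an improving epoch
    lr_decrease: float = 0.80   # multiplier (with revert) after a worsening epoch
    seed: int = 0

    def __post_init__(self):
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if min(self.initial_learning_rate, self.lr_increase, self.lr_decrease) <= 0:
            raise ValueError("rates must be positive")


class AnnScorer:
    """Two-hidden-layer tanh network with a linear scalar output.

    Weights start uniform in [-1/sqrt(fan_in), +1/sqrt(fan_in)] from the
    run seed; training is full-batch gradient descent on MSE with the
    adaptive-rate schedule of :class:`TrainConfig`.
    """

    def __init__(self, n_features: int, hidden_layers: int = 2, hidden_units: int = 16,
                 cfg: TrainConfig | None = None):
        self.cfg = cfg or TrainConfig()
        self.n_features = n_features
        rng = np.random.default_rng(self.cfg.seed)
        sizes = [n_features] + [hidden_units] * hidden_layers + [1]
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            bound = 1.0 / np.sqrt(fan_in)
            self.weights.append(rng.uniform(-bound, bound, size=(fan_in, fan_out)))
            self.biases.append(rng.uniform(-bound, bound, size=fan_out))
        self.n_iterations_ = 0
        self.loss_curve_: list[float] = []

    def _forward(self, X: np.ndarray) -> tuple[list[np.ndarray], np.ndarray]:
        activations = [X]
        a = X
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            z = a @ W + b
            a = z if i == len(self.weights) - 1 else np.tanh(z)
            activations.append(a)
        return activations, a[:, 0]

    def _gradients(self, X: np.ndarray, y: np.ndarray):
        acts, out = self._forward(X)
        n = len(y)
        delta = (2.0 / n) * (out - y)[:, None]  # d(MSE)/d(output)
        grads_w, grads_b = [], []
        for i in range(len(self.weights) - 1, -1, -1):
            a_prev = acts[i]
            grads_w.append(a_prev.T @ delta)
            grads_b.append(delta.sum(axis=0))
            if i > 0:
                delta = (delta @ self.weights[i].T) * (1.0 - acts[i] ** 2)
        grads_w.reverse()
        grads_b.reverse()
        loss = float(np.mean((out - y) ** 2))
        return grads_w, grads_b, loss

    def fit(self, X: np.ndarray, y: np.ndarray) -> "AnnScorer":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        lr = self.cfg.initial_learning_rate
        _, _, loss = self._gradients(X, y)
        for it in range(self.cfg.max_iterations):
            grads_w, grads_b, loss = self._gradients(X, y)
            if not np.isfinite(loss):
                raise TrainingError(f"loss diverged at iteration {it}")
            self.loss_curve_.append(loss)
            gnorm = np.sqrt(sum(float(np.sum(g**2)) for g in grads_w + grads_b))
            if gnorm < self.cfg.gradient_floor:
                break
            prev_w = [w.copy() for w in self.weights]
            prev_b = [b.copy() for b in self.biases]
            for w, b, gw, gb in zip(self.weights, self.biases, grads_w, grads_b):
                w -= lr * gw
                b -= lr * gb
            _, out = self._forward(X)
            new_loss = float(np.mean((out - y) ** 2))
            if not np.isfinite(new_loss):
                self.weights, self.biases = prev_w, prev_b
                raise TrainingError(
                    f"loss diverged at iteration {it}; last stable loss {loss:.4g}"
                )
            if new_loss <= loss:
                lr *= self.cfg.lr_increase
            else:
                self.weights, self.biases = prev_w, prev_b
                lr *= self.cfg.lr_decrease
            self.n_iterations_ = it + 1
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        _, out = self._forward(np.asarray(X, dtype=float))
        return out


def loso_splits(manifest_or_subjects) -> list[tuple[list[str], str]]:
    """One fold per subject: (training subjects, held-out subject)."""
    if isinstance(manifest_or_subjects, CohortManifest):
        subjects = manifest_or_subjects.subjects
    else:
        seen: dict[str, None] = {}
        for s in manifest_or_subjects:
            seen.setdefault(s, None)
        subjects = list(seen)
    if len(subjects) < 2:
        raise ValidationError("LOSO requires at least 2 subjects")
    return [([s for s in subjects if s != held], held) for held in subjects]


def fit_classifier(spec: ModelSpec, X: np.ndarray, y: np.ndarray, seed: int = 0):
    """Fit one of the discrete classifiers on (already standardized) data."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < len(set(range(int(y.min()), int(y.max()) + 1))):
        logger.info("training fold missing some classes; fitting on those present")
    hp = spec.hyperparameters
    if spec.kind == "svm":
        model = SVC(kernel=hp["kernel"], C=hp["box_constraint"],
                    decision_function_shape="ovo", random_state=seed)
    elif spec.kind == "knn":
        model = KNeighborsClassifier(n_neighbors=min(hp["n_neighbors"], len(y)),
                                     metric=hp["metric"], weights=hp["weights"])
    elif spec.kind == "dt":
        # max_splits internal nodes <=> max_leaf_nodes = max_splits + 1
        model = DecisionTreeClassifier(criterion=hp["criterion"],
                                       max_leaf_nodes=hp["max_splits"] + 1,
                                       random_state=seed)
    else:
        raise ValueError(f"fit_classifier does not handle kind {spec.kind!r}")
    return model.fit(X, y)


def fit_ann(spec: ModelSpec, cfg: TrainConfig, X: np.ndarray, y: np.ndarray) -> AnnScorer:
    """Train the continuous scorer on mean rater scores (standardized X)."""
    hp = spec.hyperparameters
    ann = AnnScorer(n_features=np.asarray(X).shape[1],
                    hidden_layers=hp["hidden_layers"],
                    hidden_units=hp["hidden_units"], cfg=cfg)
    return ann.fit(X, y)


def _standardize(train: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd[sd == 0] = 1.0
    return (train - mu) / sd, (test - mu) / sd


def run_loso(
    spec: ModelSpec,
    features: pd.DataFrame,
    subjects: Sequence[str],
    labels: Sequence[int],
    continuous_targets: Optional[Sequence[float]] = None,
    cfg: TrainConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Leave-one-subject-out predictions for one model.

    Returns a frame indexed like ``features`` with columns ``fold_id``,
    ``label`` and (for the neural scorer) ``continuous_score``.  The ANN
    label is ``clip(round(continuous), 0, 3)``.
    """
    X_all = features.to_numpy(dtype=float)
    subjects = np.asarray(subjects)
    labels = np.asarray(labels, dtype=int)
    cfg = cfg or TrainConfig(seed=seed)
    if spec.kind == "ann":
        if continuous_targets is None:
            raise ValueError("the neural scorer needs continuous targets")
        y_cont = np.asarray(continuous_targets, dtype=float)

    out = pd.DataFrame(index=features.index,
                       columns=["fold_id", "continuous_score", "label"], dtype=object)
    for fold_id, (train_subj, held) in enumerate(loso_splits(list(subjects))):
        train_mask = subjects != held
        test_mask = ~train_mask
        X_train, X_test = _standardize(X_all[train_mask], X_all[test_mask])
        if spec.kind == "ann":
            fold_cfg = TrainConfig(max_iterations=cfg.max_iterations,
                                   gradient_floor=cfg.gradient_floor,
                                   initial_learning_rate=cfg.initial_learning_rate,
                                   lr_increase=cfg.lr_increase,
                                   lr_decrease=cfg.lr_decrease,
                                   seed=cfg.seed)
            ann = fit_ann(spec, fold_cfg, X_train, y_cont[train_mask])
            cont = ann.predict(X_test)
            pred = np.clip(round_half_away(cont), 0, 3).astype(int)
            out.loc[test_mask, "continuous_score"] = cont
        else:
            model = fit_classifier(spec, X_train, labels[train_mask], seed=seed)
            pred = model.predict(X_test).astype(int)
        out.loc[test_mask, "label"] = pred
        out.loc[test_mask, "fold_id"] = fold_id
    out["fold_id"] = out["fold_id"].astype(int)
    out["label"] = out["label"].astype(int)
    out["continuous_score"] = pd.to_numeric(out["continuous_score"])
    return out


def loso_accuracy(spec: ModelSpec, features: pd.DataFrame, subjects, labels,
                  continuous_targets=None, seed: int = 0) -> float:
    preds = run_loso(spec, features, subjects, labels, continuous_targets, seed=seed)
    return float(np.mean(preds["label"].to_numpy() == np.asarray(labels, dtype=int)))


def grid_search(
    spec_space: Sequence[ModelSpec],
    features: pd.DataFrame,
    subjects,
    labels,
    continuous_targets=None,
    seed: int = 0,
    default: ModelSpec | None = None,
) -> ModelSpec:
    """Exhaustive search over a small grid of specs by LOSO accuracy.

    Ties resolve toward ``default`` when it is among the tied specs,
    otherwise toward the earlier grid entry; the result is invariant to
    enumeration order.
    """
    spec_space = list(spec_space)
    if not spec_space:
        raise ValueError("empty spec grid")
    scored = [
        (loso_accuracy(s, features, subjects, labels, continuous_targets, seed=seed), s)
        for s in spec_space
    ]
    best_acc = max(acc for acc, _ in scored)
    tied = [s for acc, s in scored if acc == best_acc]
    if default is not None:
        for s in tied:
            if s.kind == default.kind and s.hyperparameters == default.hyperparameters:
                return s
    tied.sort(key=lambda s: (s.kind, sorted(s.hyperparameters.items()).__repr__()))
    return tied[0]


def save_artifact(path, model, spec: ModelSpec, feature_names: Sequence[str],
                  scaler_mean: np.ndarray, scaler_sd: np.ndarray, seed: int) -> None:
    """Serialize a trained model with its spec, schema and scaler."""
    payload = {
        "version": ARTIFACT_VERSION,
        "spec": spec,
        "feature_names": list(feature_names),
        "scaler_mean": np.asarray(scaler_mean),
        "scaler_sd": np.asarray(scaler_sd),
        "seed": seed,
        "model": model,
    }
    with open(path, "wb") as fh:
        pickle.dump(payload, fh)


def load_artifact(path) -> dict:
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    if payload.get("version") != ARTIFACT_VERSION:
        raise SchemaError(f"artifact version {payload.get('version')} != {ARTIFACT_VERSION}")
    return payload
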