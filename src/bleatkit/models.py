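"""Classifier families for the screening protocol plus the tuned MLP.

Every family maps onto a scikit-learn estimator behind a uniform
train/predict surface with a feature-name contract and deterministic seeding.
The default MLP matches the tuned configuration: hidden layers (256, 128),
tanh, Adam at 1e-3, batch 32, L2 1e-3, early-stopping patience 10, max 500
epochs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Any, Callable

import numpy as np
from scipy.special import softmax
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis, QuadraticDiscriminantAnalysis
from sklearn.dummy import DummyClassifier
from sklearn.ensemble import (
    AdaBoostClassifier,
    ExtraTreesClassifier,
    GradientBoostingClassifier,
    HistGradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression, RidgeClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import LinearSVC
from sklearn.tree import DecisionTreeClassifier

MLP_DEFAULTS: dict[str, Any] = {
    "hidden_layer_sizes": (256, 128),
    "activation": "tanh",
    "solver": "adam",
    "learning_rate_init": 0.001,
    "batch_size": 32,
    "alpha": 0.001,
    "early_stopping": True,
    "n_iter_no_change": 10,
    "validation_fraction": 0.1,
    "max_iter": 500,
}

MLP_GRID: dict[str, list] = {
    "hidden_layer_sizes": [(100,), (100, 50), (254, 58), (256, 128), (100, 100, 100)],
    "activation": ["relu", "tanh"],
    "learning_rate_init": [0.0005, 0.001, 0.01],
    "batch_size": [32, 64, 128],
    "alpha": [0.0001, 0.001, 0.01, 0.05],
}

FAMILIES = (
    "gradient_boosted_trees",
    "hist_gradient_boosting",
    "random_forest",
    "extra_trees",
    "k_nearest_neighbors",
    "logistic",
    "lda",
    "qda",
    "ridge",
    "linear_svm",
    "naive_bayes",
    "decision_tree",
    "adaboost",
    "dummy_majority",
    "mlp",
)


@dataclass(frozen=True)
class ModelSpec:
    """Classifier family plus its hyperparameters and a seed."""

    family: str
    hyperparameters: dict[str, Any] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}; choose from {FAMILIES}")


def _build_estimator(spec: ModelSpec):
    hp = dict(spec.hyperparameters)
    seed = spec.seed
    family = spec.family
    if family == "mlp":
        params = {**MLP_DEFAULTS, **hp}
        return MLPClassifier(random_state=seed, **params)
    if family == "gradient_boosted_trees":
        return GradientBoostingClassifier(random_state=seed, **hp)
    if family == "hist_gradient_boosting":
        return HistGradientBoostingClassifier(random_state=seed, **hp)
    if family == "random_forest":
        return RandomForestClassifier(random_state=seed, **hp)
    if family == "extra_trees":
        return ExtraTreesClassifier(random_state=seed, **hp)
    if family == "k_nearest_neighbors":
        return KNeighborsClassifier(**hp)
    if family == "logistic":
        return LogisticRegression(max_iter=2000, random_state=seed, **hp)
    if family == "lda":
        return LinearDiscriminantAnalysis(**hp)
    if family == "qda":
        return QuadraticDiscriminantAnalysis(**hp)
    if family == "ridge":
        return RidgeClassifier(random_state=seed, **hp)
    if family == "linear_svm":
        return LinearSVC(random_state=seed, **hp)
    if family == "naive_bayes":
        return GaussianNB(**hp)
    if family == "decision_tree":
        return DecisionTreeClassifier(random_state=seed, **hp)
    if family == "adaboost":
        return AdaBoostClassifier(random_state=seed, **hp)
    if family == "dummy_majority":
        return DummyClassifier(strategy="most_frequent")
    raise ValueError(f"unknown family {family!r}")


@dataclass
class TrainedModel:
    """A fitted predictor with its label order and feature-name contract."""

    spec: ModelSpec
    estimator: Any
    classes: np.ndarray
    feature_names: list[str] | None = None
    metadata: dict[str, Any] = field(default_factory=dict)

    def _check_contract(self, X, feature_names: list[str] | None) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (rows x features)")
        n_expected = self.estimator.n_features_in_
        if X.shape[1] != n_expected:
            raise ValueError(f"feature count mismatch: model expects {n_expected}, got {X.shape[1]}")
        if feature_names is not None and self.feature_names is not None:
            if list(feature_names) != list(self.feature_names):
                missing = set(self.feature_names) - set(feature_names)
                raise ValueError(f"feature-name contract mismatch (missing or reordered: {sorted(missing)})")
        return X


def train(spec: ModelSpec, X_train, y_train, feature_names: list[str] | None = None) -> TrainedModel:
    """Fit one classifier; label order is alphabetical (scikit-learn sorted classes)."""
    X = np.asarray(X_train, dtype=np.float64)
    y = np.asarray(y_train)
    if not np.all(np.isfinite(X)):
        raise ValueError("X_train contains NaN/Inf")
    if len(np.unique(y)) < 2:
        raise ValueError("training requires at least 2 classes")
    est = _build_estimator(spec)
    est.fit(X, y)
    return TrainedModel(spec=spec, estimator=est, classes=np.asarray(est.classes_), feature_names=feature_names)


def predict(m: TrainedModel, X, feature_names: list[str] | None = None) -> np.ndarray:
    X = m._check_contract(X, feature_names)
    proba = predict_proba(m, X)
    return m.classes[np.argmax(proba, axis=1)]


def predict_proba(m: TrainedModel, X, feature_names: list[str] | None = None) -> np.ndarray:
    """Per-class probabilities; margin classifiers go through a softmax."""
    X = m._check_contract(X, feature_names)
    if hasattr(m.estimator, "predict_proba"):
        proba = m.estimator.predict_proba(X)
    else:
        scores = m.estimator.decision_function(X)
        if scores.ndim == 1:  # binary margin
            scores = np.stack([-scores, scores], axis=1)
        proba = softmax(scores, axis=1)
    proba = np.asarray(proba, dtype=np.float64)
    if not np.all(np.isfinite(proba)):
        raise ArithmeticError("non-finite class probabilities")
    return proba


def _cv_accuracy(spec: ModelSpec, X, y, folds: int, seed: int) -> float:
    y = np.asarray(y)
    _, counts = np.unique(y, return_counts=True)
    if folds > counts.min():
        raise ValueError(f"fold count {folds} exceeds the smallest class size {counts.min()}")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs = []
    for tr, va in skf.split(X, y):
        m = train(spec, np.asarray(X)[tr], y[tr])
        accs.append(float(np.mean(predict(m, np.asarray(X)[va]) == y[va])))
    return float(np.mean(accs))


def _network_size(hidden) -> int:
    if isinstance(hidden, int):
        return hidden
    return int(sum(hidden))


def grid_search_mlp(
    X_train,
    y_train,
    grids: dict[str, list] | None = None,
    folds: int = 3,
    seed: int = 0,
) -> ModelSpec:
    """Exhaustive grid search over MLP hyperparameters with stratified k-fold CV.

    Ties are broken toward the smaller network, then the lower learning rate.
    """
    if grids is None:
        grids = MLP_GRID
    keys = sorted(grids)
    best: tuple | None = None
    best_spec: ModelSpec | None = None
    for combo in itertools.product(*(grids[k] for k in keys)):
        hp = dict(zip(keys, combo))
        spec = ModelSpec(family="mlp", hyperparameters=hp, seed=seed)
        acc = _cv_accuracy(spec, X_train, y_train, folds, seed)
        key = (
            -acc,
            _network_size(hp.get("hidden_layer_sizes", MLP_DEFAULTS["hidden_layer_sizes"])),
            hp.get("learning_rate_init", MLP_DEFAULTS["learning_rate_init"]),
        )
        if best is None or key < best:
            best, best_spec = key, spec
    assert best_spec is not None
    return best_spec


def random_search(
    base_spec: ModelSpec,
    X_train,
    y_train,
    param_distributions: dict[str, list],
    n_trials: int = 10,
    folds: int = 3,
    seed: int = 0,
    strategy: Callable[..., dict] | None = None,
) -> ModelSpec:
    """Stochastic hyperparameter search that never underperforms the base spec.

    The sampling strategy is pluggable (random draw by default), standing in
    for fancier Bayesian tuners; the base spec is always evaluated and kept
    if nothing beats it.
    """
    rng = np.random.default_rng(seed)
    if strategy is None:
        def strategy(dists, rng=rng):
            return {k: v[rng.integers(len(v))] for k, v in dists.items()}

    best_spec = base_spec
    best_acc = _cv_accuracy(base_spec, X_train, y_train, folds, seed)
    for _ in range(n_trials):
        hp = {**base_spec.hyperparameters, **strategy(param_distributions)}
        spec = replace(base_spec, hyperparameters=hp)
        acc = _cv_accuracy(spec, X_train, y_train, folds, seed)
        if acc > best_acc:
            best_acc, best_spec = acc, spec
    return best_spec
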