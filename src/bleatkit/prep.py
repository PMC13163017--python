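"""Stratified splitting, SMOTE balancing, z-score standardization, selection.

All four operations accept only the partition they are allowed to see: SMOTE,
scaler fitting and importance fitting take training rows exclusively, which
keeps test leakage impossible by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import GradientBoostingClassifier

_EPS = 1e-12


@dataclass(frozen=True)
class SplitIndices:
    """Disjoint train/test row indices covering the full set."""

    train: np.ndarray
    test: np.ndarray

    def __post_init__(self) -> None:
        train = np.asarray(self.train, dtype=np.int64)
        test = np.asarray(self.test, dtype=np.int64)
        if np.intersect1d(train, test).size:
            raise ValueError("train and test indices overlap")
        object.__setattr__(self, "train", train)
        object.__setattr__(self, "test", test)


@dataclass
class ScalerParams:
    """Per-feature mean and population std fitted on training data."""

    mu: np.ndarray | None = None
    sigma: np.ndarray | None = None

    @property
    def fitted(self) -> bool:
        return self.mu is not None


def stratified_split(y, test_fraction: float = 0.2, seed: int = 0) -> SplitIndices:
    """Per-class largest-remainder allocation of the test partition.

    Test counts deviate from exact proportionality by less than one clip per
    class; assignment within a class is randomized by ``seed``.
    """
    y = np.asarray(y)
    if not (0.0 < test_fraction < 1.0):
        raise ValueError("test_fraction must be in (0, 1)")
    classes, counts = np.unique(y, return_counts=True)
    for cls, n in zip(classes, counts):
        if n < 2:
            raise ValueError(f"class {cls!r} has only {n} member(s); need >= 2 to split")

    quotas = counts * test_fraction
    base = np.floor(quotas).astype(int)
    target_total = round(len(y) * test_fraction)
    remainder_order = np.argsort(-(quotas - base), kind="stable")
    short = target_total - int(base.sum())
    alloc = base.copy()
    for i in range(max(short, 0)):
        alloc[remainder_order[i % len(classes)]] += 1
    # never empty the train side of a class
    alloc = np.minimum(alloc, counts - 1)

    rng = np.random.default_rng(seed)
    test_idx: list[np.ndarray] = []
    for cls, n_test in zip(classes, alloc):
        members = np.nonzero(y == cls)[0]
        test_idx.append(rng.permutation(members)[:n_test])
    test = np.sort(np.concatenate(test_idx))
    train = np.setdiff1d(np.arange(len(y)), test)
    return SplitIndices(train=train, test=test)


def smote_balance(X_train, y_train, k: int = 5, seed: int = 0):
    """SMOTE: oversample each minority class to the majority count.

    Synthetic rows are ``x_i + u * (x_nn - x_i)`` with ``u ~ U(0, 1)`` and
    ``x_nn`` a random one of the ``k`` nearest same-class neighbors
    (Euclidean); ``k`` falls back to ``n_c - 1`` for tiny classes.
    """
    X = np.asarray(X_train, dtype=np.float64)
    y = np.asarray(y_train)
    classes, counts = np.unique(y, return_counts=True)
    majority = int(counts.max())
    rng = np.random.default_rng(seed)

    new_X: list[np.ndarray] = [X]
    new_y: list[np.ndarray] = [y]
    for cls, n_c in zip(classes, counts):
        n_needed = majority - int(n_c)
        if n_needed == 0:
            continue
        if n_c < 2:
            raise ValueError(f"class {cls!r} has a single sample; SMOTE cannot interpolate")
        members = X[y == cls]
        k_eff = min(k, int(n_c) - 1)
        # pairwise distances within the class (classes are small here)
        d2 = ((members[:, None, :] - members[None, :, :]) ** 2).sum(axis=2)
        np.fill_diagonal(d2, np.inf)
        nn_idx = np.argsort(d2, axis=1)[:, :k_eff]

        base = rng.integers(0, len(members), size=n_needed)
        pick = rng.integers(0, k_eff, size=n_needed)
        u = rng.uniform(0.0, 1.0, size=n_needed)
        x_i = members[base]
        x_nn = members[nn_idx[base, pick]]
        synthetic = x_i + u[:, None] * (x_nn - x_i)
        new_X.append(synthetic)
        new_y.append(np.full(n_needed, cls, dtype=y.dtype))
    return np.vstack(new_X), np.concatenate(new_y)


def fit_scaler(X_train) -> ScalerParams:
    """Fit z-score parameters (mean, population std) on training rows only.

    Zero-variance features get sigma = 1 so they standardize to exactly 0.
    """
    X = np.asarray(X_train, dtype=np.float64)
    mu = X.mean(axis=0)
    sigma = X.std(axis=0)  # ddof=0
    sigma = np.where(sigma > _EPS, sigma, 1.0)
    return ScalerParams(mu=mu, sigma=sigma)


def apply_scaler(params: ScalerParams, X) -> np.ndarray:
    """z = (x - mu) / sigma, elementwise."""
    if not params.fitted:
        raise RuntimeError("scaler has not been fitted")
    X = np.asarray(X, dtype=np.float64)
    return (X - params.mu) / params.sigma


def select_features(
    X_train,
    y_train,
    estimator=None,
    threshold: float | str = "mean",
    seed: int = 0,
) -> np.ndarray:
    """Importance-threshold feature selection with a boosted-tree estimator.

    Features whose fitted importance is >= the threshold (default: the mean
    importance) are retained, in schema order.
    """
    X = np.asarray(X_train, dtype=np.float64)
    y = np.asarray(y_train)
    if len(np.unique(y)) < 2:
        raise ValueError("need at least 2 classes for importance fitting")
    if estimator is None:
        estimator = GradientBoostingClassifier(n_estimators=50, max_depth=3, random_state=seed)
    estimator.fit(X, y)
    importances = np.asarray(estimator.feature_importances_, dtype=np.float64)
    if not np.any(importances > 0):
        raise ValueError("all feature importances are zero; selection is undefined")
    cut = float(np.mean(importances)) if threshold == "mean" else float(threshold)
    selected = np.nonzero(importances >= cut)[0]
    if selected.size == 0:
        raise ValueError(f"threshold {cut:.6g} exceeds the maximum importance; empty selection")
    return selected
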