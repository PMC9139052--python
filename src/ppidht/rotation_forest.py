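"""Rotation Forest: tree ensemble on block-diagonal PCA rotations.

Each of the L base trees sees the training data through its own rotation
matrix R_i, assembled as follows: the n features are randomly partitioned
into K disjoint subsets; for each subset a bootstrap draw of 75% of the
training objects is taken and principal components are fitted to those
objects restricted to the subset's columns; all components are retained, so
each diagonal block is a full orthonormal basis and R_i is an orthogonal
n x n matrix (information-preserving).  Tree i is then a CART decision tree
(Gini, unlimited depth) trained on X @ R_i.  Prediction averages the trees'
class posteriors (mean combination) and takes the arg-max class, ties broken
toward the class listed first in ``classes_``.

The per-subset PCA is an eigendecomposition of the bootstrap-sample
covariance; eigenvectors are ordered by descending eigenvalue and sign-fixed
so the largest-magnitude loading of each component is positive, which makes
rotations reproducible across runs and platforms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional

import joblib
import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

logger = logging.getLogger(__name__)

__all__ = [
    "FeaturePartition",
    "partition_features",
    "fit_rotation",
    "RotationForestClassifier",
    "rof_fit",
    "rof_predict",
    "rof_predict_proba",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class FeaturePartition:
    """Disjoint index groups covering features 0..n-1."""

    groups: tuple

    def __post_init__(self) -> None:
        all_idx = np.concatenate(self.groups)
        n = all_idx.size
        if not np.array_equal(np.sort(all_idx), np.arange(n)):
            raise ValueError("groups must be disjoint and cover 0..n-1")

    @property
    def n_features(self) -> int:
        return sum(g.size for g in self.groups)


def partition_features(n: int, k: int, rng: np.random.Generator) -> FeaturePartition:
    """Randomly permute features 0..n-1 and cut into K consecutive chunks.

    Each of the first K-1 groups has u = n // K features; the last group
    absorbs any remainder.
    """
    if not 1 <= k <= n:
        raise ValueError(f"need 1 <= K <= n, got K={k}, n={n}")
    perm = rng.permutation(n)
    u = n // k
    groups = [perm[i * u : (i + 1) * u] for i in range(k - 1)]
    groups.append(perm[(k - 1) * u :])
    return FeaturePartition(groups=tuple(np.sort(g) for g in groups))


def _pca_basis(block: np.ndarray) -> np.ndarray:
    """Orthonormal principal-axes basis (columns) of a sample block.

    Eigendecomposition of the sample covariance; components ordered by
    descending eigenvalue; each component's largest-|loading| entry made
    positive.  A fully degenerate (zero-variance) block falls back to the
    identity so fitting never fails.
    """
    u = block.shape[1]
    centered = block - block.mean(axis=0)
    denom = max(block.shape[0] - 1, 1)
    cov = centered.T @ centered / denom
    total_var = float(np.trace(cov))
    if not np.isfinite(total_var) or total_var <= 1e-12:
        logger.warning(
            "zero-variance feature block (%d features); substituting identity", u
        )
        return np.eye(u)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    basis = eigvecs[:, order]
    # Deterministic sign: largest-magnitude loading of each component positive.
    flips = np.sign(basis[np.argmax(np.abs(basis), axis=0), np.arange(u)])
    flips[flips == 0] = 1.0
    return basis * flips


def fit_rotation(
    X: np.ndarray,
    partition: FeaturePartition,
    bootstrap_frac: float = 0.75,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Fit one block-diagonal rotation matrix for a feature partition.

    For each feature group a bootstrap sample (with replacement) of
    ``ceil(bootstrap_frac * N)`` objects is drawn and a full PCA basis fitted
    on its columns; the blocks are placed at the groups' own row/column
    indices, which realizes the column rearrangement back to original
    feature order.  Returns an n x n orthogonal matrix R with
    ``X_rotated = X @ R``.
    """
    if rng is None:
        rng = np.random.default_rng()
    if not 0.0 < bootstrap_frac <= 1.0:
        raise ValueError("bootstrap_frac must be in (0, 1]")
    X = np.asarray(X, dtype=float)
    n_samples, n_features = X.shape
    if n_features != partition.n_features:
        raise ValueError("partition does not match feature count")
    n_boot = int(np.ceil(bootstrap_frac * n_samples))
    R = np.zeros((n_features, n_features))
    for group in partition.groups:
        idx = rng.integers(0, n_samples, size=n_boot)
        R[np.ix_(group, group)] = _pca_basis(X[np.ix_(idx, group)])
    return R


class RotationForestClassifier(ClassifierMixin, BaseEstimator):
    """Rotation Forest binary classifier.

    Parameters
    ----------
    n_estimators : int, default 30
        Number of trees L.
    n_subsets : int, default 20
        Number of feature subsets K per tree (20 evenly divides the
        400-feature pair descriptor).
    bootstrap_frac : float, default 0.75
        Fraction of objects drawn (with replacement) for each per-subset PCA.
    random_state : int or numpy Generator, optional
        Seeds feature partitioning, bootstraps, and the base trees.

    Attributes
    ----------
    classes_ : ndarray of the two class labels, sorted ascending.
    trees_ : list of fitted decision trees.
    rotations_ : list of n x n rotation matrices, one per tree.
    partitions_ : list of FeaturePartition, one per tree.
    """

    def __init__(
        self,
        n_estimators: int = 30,
        n_subsets: int = 20,
        bootstrap_frac: float = 0.75,
        random_state=None,
    ):
        self.n_estimators = n_estimators
        self.n_subsets = n_subsets
        self.bootstrap_frac = bootstrap_frac
        self.random_state = random_state

    def _rng(self) -> np.random.Generator:
        if isinstance(self.random_state, np.random.Generator):
            return self.random_state
        return np.random.default_rng(self.random_state)

    def fit(self, X, y) -> "RotationForestClassifier":
        X, y = check_X_y(X, y)
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        if self.classes_.size < 2:
            raise ValueError("y contains a single class; need two")
        if self.classes_.size > 2:
            raise ValueError("binary classification only")
        if self.n_estimators < 1:
            raise ValueError("n_estimators must be >= 1")
        n_features = X.shape[1]
        if self.n_subsets > n_features:
            raise ValueError(
                f"n_subsets={self.n_subsets} exceeds feature count {n_features}"
            )
        rng = self._rng()
        self.n_features_in_ = n_features
        self.partitions_: List[FeaturePartition] = []
        self.rotations_: List[np.ndarray] = []
        self.trees_: List[DecisionTreeClassifier] = []
        for _ in range(self.n_estimators):
            part = partition_features(n_features, self.n_subsets, rng)
            R = fit_rotation(X, part, self.bootstrap_frac, rng)
            tree = DecisionTreeClassifier(
                criterion="gini",
                random_state=int(rng.integers(0, 2**31 - 1)),
            )
            tree.fit(X @ R, y_enc)
            self.partitions_.append(part)
            self.rotations_.append(R)
            self.trees_.append(tree)
        return self

    def _check_X(self, X) -> np.ndarray:
        check_is_fitted(self, "trees_")
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, model expects {self.n_features_in_}"
            )
        return X

    def predict_proba(self, X) -> np.ndarray:
        """Mean-combination class confidences: average of tree posteriors.

        Each row is non-negative and sums to 1.
        """
        X = self._check_X(X)
        acc = np.zeros((X.shape[0], self.classes_.size))
        for tree, R in zip(self.trees_, self.rotations_):
            proba = tree.predict_proba(X @ R)
            for col, cls_idx in enumerate(tree.classes_):
                acc[:, int(cls_idx)] += proba[:, col]
        return acc / len(self.trees_)

    def predict(self, X) -> np.ndarray:
        """Class with the highest mean confidence; a tie goes to the class
        listed first in ``classes_``."""
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]


# ---------------------------------------------------------------------------
# Thin functional wrappers
# ---------------------------------------------------------------------------


def rof_fit(
    X,
    y,
    n_estimators: int = 30,
    n_subsets: int = 20,
    bootstrap_frac: float = 0.75,
    random_state=None,
) -> RotationForestClassifier:
    return RotationForestClassifier(
        n_estimators=n_estimators,
        n_subsets=n_subsets,
        bootstrap_frac=bootstrap_frac,
        random_state=random_state,
    ).fit(X, y)


def rof_predict_proba(model: RotationForestClassifier, X) -> np.ndarray:
    return model.predict_proba(X)


def rof_predict(model: RotationForestClassifier, X) -> np.ndarray:
    return model.predict(X)


def save_model(model: RotationForestClassifier, path) -> None:
    """Persist a fitted model (rotations, trees, metadata) to one file."""
    check_is_fitted(model, "trees_")
    joblib.dump(model, path)


def load_model(path) -> RotationForestClassifier:
    model = joblib.load(path)
    if not isinstance(model, RotationForestClassifier):
        raise TypeError(f"{path} does not contain a RotationForestClassifier")
    return model
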