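"""Soft-margin RBF-kernel SVM classification and the tuning objective.

The classifier solves the usual soft-margin dual with kernel
k(x1, x2) = exp(-g ||x1 - x2||^2); multiclass problems are handled
one-vs-one with majority voting.  The quadratic program itself is delegated
to libsvm via scikit-learn; this module owns the hyperparameter
parameterization and the cross-validated fitness that the sparrow search
optimizer maximizes.

Hyperparameters are searched in log10 space: log10 C in [-2, 3] and
log10 g in [-4, 2] by default, the standard parameterization for scale
parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .issa import SearchSpace

__all__ = [
    "SvmHyperparams",
    "RbfSvmClassifier",
    "default_search_space",
    "decode_position",
    "cv_fitness",
    "make_cv_fitness",
]

#: Default (log10 C, log10 g) search bounds.
LOG_C_BOUNDS = (-2.0, 3.0)
LOG_G_BOUNDS = (-4.0, 2.0)


@dataclass(frozen=True)
class SvmHyperparams:
    """Regularization strength C and RBF width g, both strictly positive."""

    C: float
    g: float

    def __post_init__(self) -> None:
        if self.C <= 0 or self.g <= 0:
            raise ValueError("C and g must be positive")


def default_search_space() -> SearchSpace:
    """Box over (log10 C, log10 g) used by the metaheuristic tuner."""
    return SearchSpace(
        lower=np.array([LOG_C_BOUNDS[0], LOG_G_BOUNDS[0]]),
        upper=np.array([LOG_C_BOUNDS[1], LOG_G_BOUNDS[1]]),
    )


def decode_position(position: np.ndarray) -> SvmHyperparams:
    """Map an optimizer position (log10 C, log10 g) to hyperparameters."""
    position = np.asarray(position, dtype=float).ravel()
    if position.size != 2:
        raise ValueError("position must have exactly 2 entries")
    return SvmHyperparams(C=float(10.0 ** position[0]), g=float(10.0 ** position[1]))


class RbfSvmClassifier(BaseEstimator, ClassifierMixin):
    """One-vs-one soft-margin SVM with the kernel exp(-g ||x1 - x2||^2).

    Thin estimator over libsvm keeping the (C, g) parameterization used
    throughout this package (g multiplies the squared distance directly).
    Ties in the one-vs-one vote resolve deterministically by class order.
    """

    def __init__(self, C: float = 1.0, g: float = 0.1):
        self.C = C
        self.g = g

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite feature values")
        if np.unique(y).size < 2:
            raise ValueError("training data must contain at least 2 classes")
        hp = SvmHyperparams(C=self.C, g=self.g)
        self.svc_ = SVC(
            C=hp.C,
            kernel="rbf",
            gamma=hp.g,
            decision_function_shape="ovo",
            break_ties=False,
            cache_size=200,
        )
        self.svc_.fit(X, y)
        self.classes_ = self.svc_.classes_
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "svc_")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got shape {X.shape}"
            )
        if X.shape[0] == 0:
            return np.empty(0, dtype=self.classes_.dtype)
        return self.svc_.predict(X)

    def decision_function(self, X):
        check_is_fitted(self, "svc_")
        return self.svc_.decision_function(np.asarray(X, dtype=float))

    @property
    def dual_coef_(self):
        check_is_fitted(self, "svc_")
        return self.svc_.dual_coef_

    @property
    def support_vectors_(self):
        check_is_fitted(self, "svc_")
        return self.svc_.support_vectors_

    @property
    def intercept_(self):
        check_is_fitted(self, "svc_")
        return self.svc_.intercept_


def _cv_splitter(y: np.ndarray, k_folds: int, seed: int) -> StratifiedKFold:
    """Stratified k-fold that never leaves a class out of a training fold;
    k is reduced (with a warning) when the rarest class has < k members."""
    _, counts = np.unique(y, return_counts=True)
    k = min(k_folds, int(counts.min()))
    if k < 2:
        raise ValueError("every class needs at least 2 samples for CV")
    if k < k_folds:
        import warnings

        warnings.warn(
            f"reducing CV folds from {k_folds} to {k}: rarest class has "
            f"{int(counts.min())} samples",
            stacklevel=3,
        )
    return StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)


def cv_fitness(
    X: np.ndarray,
    y: np.ndarray,
    position: np.ndarray,
    k_folds: int = 5,
    seed: int = 0,
) -> float:
    """Mean stratified k-fold held-out accuracy for one optimizer position.

    This is the fitness the sparrow search maximizes; it is deterministic
    given (X, y, position, seed) and invariant to sample order (rows are
    canonically re-ordered before fold assignment).
    """
    hp = decode_position(position)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    _, y_codes = np.unique(y, return_inverse=True)
    order = np.lexsort(tuple(X.T) + (y_codes,))
    X, y = X[order], y[order]
    clf = RbfSvmClassifier(C=hp.C, g=hp.g)
    cv = _cv_splitter(y, k_folds, seed)
    scores = cross_val_score(clf, X, y, cv=cv, scoring="accuracy")
    return float(scores.mean())


def make_cv_fitness(X, y, k_folds: int = 5, seed: int = 0, max_samples: int | None = None):
    """Bind (X, y) into a position -> accuracy callable for the optimizer.

    ``max_samples`` caps the tuning set by stratified subsampling — the
    hyperparameter landscape is estimated on a subset when the full
    training set would make each fitness evaluation too costly.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if max_samples is not None and X.shape[0] > max_samples:
        rng = np.random.default_rng(seed)
        idx = []
        classes, inv = np.unique(y, return_inverse=True)
        per_class = max(2, max_samples // classes.size)
        for c in range(classes.size):
            members = np.flatnonzero(inv == c)
            take = min(per_class, members.size)
            idx.append(rng.choice(members, take, replace=False))
        idx = np.sort(np.concatenate(idx))
        X, y = X[idx], y[idx]

    def fitness(position: np.ndarray) -> float:
        return cv_fitness(X, y, position, k_folds=k_folds, seed=seed)

    return fitness
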