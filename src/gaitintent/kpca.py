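"""Kernel principal component analysis with an RBF kernel.

PCA is performed implicitly in the kernel-induced feature space: the n x n
kernel matrix K, K_ij = exp(-||x_i - x_j||^2 / (2 sigma^2)), is double-
centered (the feature-space maps are not zero-mean, so centering must be
done on K itself), eigendecomposed, and the eigenvectors alpha_k rescaled
so the implicit feature-space eigenvectors have unit norm:
lambda_k * (alpha_k' alpha_k) = 1.  A new point x projects onto component k
as t_k(x) = sum_j alpha_jk * k_centered(x_j, x).

The transformer follows scikit-learn conventions (``fit`` / ``transform``,
trailing-underscore fitted attributes) and composes with sklearn pipelines.
A ``kernel="linear"`` code path exists solely so the implementation can be
cross-checked against ordinary PCA.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist, pdist
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

__all__ = ["GaitKPCA", "rbf_kernel", "center_kernel", "median_heuristic_sigma"]


def rbf_kernel(x: np.ndarray, y: np.ndarray, sigma: float) -> float:
    """Gaussian RBF kernel exp(-||x - y||^2 / (2 sigma^2)) for two vectors."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("vectors must have equal dimension")
    return float(np.exp(-np.sum((x - y) ** 2) / (2.0 * sigma**2)))


def _kernel_matrix(X: np.ndarray, Y: np.ndarray, kernel: str, sigma: float) -> np.ndarray:
    if kernel == "rbf":
        d2 = cdist(X, Y, metric="sqeuclidean")
        return np.exp(-d2 / (2.0 * sigma**2))
    if kernel == "linear":
        return X @ Y.T
    raise ValueError(f"unknown kernel {kernel!r}")


def center_kernel(
    K: np.ndarray,
    mode: str = "train",
    row_means: np.ndarray | None = None,
    grand_mean: float | None = None,
) -> np.ndarray | tuple[np.ndarray, np.ndarray, float]:
    """Double-center a kernel matrix.

    ``mode="train"``: K' = K - 1_n K - K 1_n + 1_n K 1_n (1_n = matrix of
    1/n); returns ``(K_centered, training_row_means, grand_mean)`` so new
    points can be centered consistently.  ``mode="cross"``: K is
    [m x n_train]; centers against the stored training statistics.
    """
    K = np.asarray(K, dtype=float)
    if mode == "train":
        if K.shape[0] != K.shape[1]:
            raise ValueError("training kernel matrix must be square")
        means = K.mean(axis=0)
        grand = float(K.mean())
        Kc = K - means[None, :] - means[:, None] + grand
        return Kc, means, grand
    if mode == "cross":
        if row_means is None or grand_mean is None:
            raise ValueError("cross-mode centering needs training statistics")
        cross_means = K.mean(axis=1, keepdims=True)
        return K - row_means[None, :] - cross_means + grand_mean
    raise ValueError(f"unknown centering mode {mode!r}")


def median_heuristic_sigma(
    X: np.ndarray, max_points: int = 500, seed: int = 0
) -> float:
    """Median pairwise Euclidean distance over a subsample of the rows."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] > max_points:
        rng = np.random.default_rng(seed)
        X = X[rng.choice(X.shape[0], max_points, replace=False)]
    d = pdist(X)
    med = float(np.median(d)) if d.size else 1.0
    return med if med > 0 else 1.0


class GaitKPCA(BaseEstimator, TransformerMixin):
    """Kernel-PCA dimensionality reducer.

    Parameters
    ----------
    sigma : float or "median", default "median"
        RBF bandwidth; ``"median"`` uses the median pairwise distance of a
        (up to) 500-row training subsample.
    n_components : int, optional
        Fixed number of retained components.  Mutually exclusive with
        ``variance_threshold``.
    variance_threshold : float, default 0.95
        Retain the smallest p whose cumulative contribution rate
        C(lambda_j) = lambda_j / sum(lambda) reaches this fraction.
        Ignored when ``n_components`` is given.
    kernel : {"rbf", "linear"}, default "rbf"
        "linear" exists for cross-checking against ordinary PCA.

    Attributes
    ----------
    X_train_ : ndarray of shape (n, d)
    sigma_ : float
    alphas_ : ndarray of shape (n, p)
        Coefficient vectors, scaled so lambda_k * ||alpha_k||^2 = 1.
    lambdas_ : ndarray of shape (p,)
        Kernel-matrix eigenvalues, non-increasing.
    contribution_ : ndarray of shape (n,)
        Contribution rate of every component in percent (sums to 100).
    n_components_ : int
    """

    def __init__(
        self,
        sigma: float | str = "median",
        n_components: int | None = None,
        variance_threshold: float = 0.95,
        kernel: str = "rbf",
    ):
        self.sigma = sigma
        self.n_components = n_components
        self.variance_threshold = variance_threshold
        self.kernel = kernel

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        n = X.shape[0]
        if n < 2:
            raise ValueError("kernel PCA needs at least 2 samples")
        if self.sigma == "median":
            sigma = median_heuristic_sigma(X)
        else:
            sigma = float(self.sigma)
            if sigma <= 0:
                raise ValueError("sigma must be positive")
        K = _kernel_matrix(X, X, self.kernel, sigma)
        Kc, row_means, grand = center_kernel(K, mode="train")
        lam, vec = np.linalg.eigh(Kc)
        lam, vec = lam[::-1], vec[:, ::-1]  # descending
        if lam.size and lam[0] > 0 and np.min(lam) < -1e-8 * lam[0]:
            raise np.linalg.LinAlgError(
                "kernel matrix eigendecomposition produced significantly "
                "negative eigenvalues"
            )
        lam = np.clip(lam, 0.0, None)
        total = lam.sum()
        contribution = 100.0 * lam / total if total > 0 else np.zeros_like(lam)

        if self.n_components is not None:
            p = int(self.n_components)
            if not 1 <= p <= n:
                raise ValueError(f"n_components={p} outside [1, {n}]")
        else:
            tau = 100.0 * float(self.variance_threshold)
            cum = np.cumsum(contribution)
            p = int(np.searchsorted(cum, tau - 1e-9)) + 1
            p = min(p, int(np.sum(lam > 1e-12 * max(lam[0], 1.0))) or 1)

        alphas = vec[:, :p].copy()
        nz = lam[:p] > 0
        alphas[:, nz] /= np.sqrt(lam[:p][nz])  # lambda * ||alpha||^2 = 1
        alphas[:, ~nz] = 0.0

        self.X_train_ = X
        self.sigma_ = sigma
        self.alphas_ = alphas
        self.lambdas_ = lam[:p]
        self.all_lambdas_ = lam
        self.contribution_ = contribution
        self.row_means_ = row_means
        self.grand_mean_ = grand
        self.n_components_ = p
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "alphas_")
        X = check_array(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features; model was fitted with "
                f"{self.n_features_in_}"
            )
        K = _kernel_matrix(X, self.X_train_, self.kernel, self.sigma_)
        Kc = center_kernel(
            K, mode="cross", row_means=self.row_means_, grand_mean=self.grand_mean_
        )
        return Kc @ self.alphas_

    def fit_transform(self, X, y=None, **fit_params):
        return self.fit(X).transform(X)
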