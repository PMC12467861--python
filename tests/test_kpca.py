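"""Kernel PCA: kernel math, centering, eigenstructure, PCA equivalence."""

import numpy as np
import pytest

from gaitintent.kpca import GaitKPCA, center_kernel, rbf_kernel


class TestRbfKernel:
    def test_zero_distance(self):
        x = np.array([1.0, 2.0, 3.0])
        assert rbf_kernel(x, x, sigma=0.5) == 1.0

    def test_characteristic_distance(self):
        sigma = 1.3
        x = np.zeros(2)
        y = np.array([sigma * np.sqrt(2.0), 0.0])  # ||x-y||^2 = 2 sigma^2
        assert rbf_kernel(x, y, sigma) == pytest.approx(np.exp(-1.0))

    def test_large_sigma_limit(self):
        x, y = np.array([1.0, -2.0]), np.array([4.0, 5.0])
        assert rbf_kernel(x, y, sigma=1e8) == pytest.approx(1.0, abs=1e-12)

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            rbf_kernel(np.zeros(2), np.ones(2), sigma=0.0)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            rbf_kernel(np.zeros(2), np.zeros(3), sigma=1.0)


class TestCenterKernel:
    def test_row_sums_vanish(self):
        rng = np.random.default_rng(0)
        A = rng.standard_normal((5, 3))
        K = A @ A.T  # PSD
        Kc, _, _ = center_kernel(K, "train")
        assert np.max(np.abs(Kc.sum(axis=0))) < 1e-10
        assert np.max(np.abs(Kc.sum(axis=1))) < 1e-10

    def test_idempotent_on_centered(self):
        rng = np.random.default_rng(1)
        A = rng.standard_normal((6, 4))
        Kc, _, _ = center_kernel(A @ A.T, "train")
        Kcc, _, _ = center_kernel(Kc, "train")
        assert np.max(np.abs(Kcc - Kc)) < 1e-10

    def test_single_point(self):
        Kc, _, _ = center_kernel(np.array([[1.0]]), "train")
        assert Kc == pytest.approx(np.zeros((1, 1)))

    def test_cross_mode_requires_stats(self):
        with pytest.raises(ValueError, match="training statistics"):
            center_kernel(np.ones((2, 3)), "cross")

    def test_cross_mode_matches_train_on_same_data(self):
        rng = np.random.default_rng(2)
        A = rng.standard_normal((5, 3))
        K = A @ A.T
        Kc, means, grand = center_kernel(K, "train")
        Kx = center_kernel(K, "cross", row_means=means, grand_mean=grand)
        np.testing.assert_allclose(Kx, Kc, atol=1e-12)


class TestFit:
    def test_identical_rows_degenerate(self):
        X = np.tile([1.0, 2.0, 3.0], (6, 1))
        model = GaitKPCA(sigma=1.0, n_components=3).fit(X)
        assert np.all(model.lambdas_ < 1e-10)

    def test_full_variance_retention_gives_rank(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((12, 4))
        model = GaitKPCA(sigma=2.0, variance_threshold=1.0).fit(X)
        lam = model.all_lambdas_
        rank = int(np.sum(lam > 1e-12 * lam[0]))
        assert model.n_components_ == rank

    def test_contribution_rates(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((15, 5))
        model = GaitKPCA(sigma=1.5).fit(X)
        c = model.contribution_
        assert np.all(c >= 0)
        assert np.all(np.diff(c) <= 1e-12)  # sorted non-increasing
        assert c.sum() == pytest.approx(100.0, abs=1e-6)

    def test_eigenvalues_sorted_nonnegative(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((20, 6))
        model = GaitKPCA(sigma="median").fit(X)
        lam = model.lambdas_
        assert np.all(lam >= 0)
        assert np.all(np.diff(lam) <= 1e-12)

    def test_alpha_normalization(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((10, 3))
        model = GaitKPCA(sigma=1.0, n_components=4).fit(X)
        for k in range(model.n_components_):
            if model.lambdas_[k] > 1e-10:
                norm = model.lambdas_[k] * model.alphas_[:, k] @ model.alphas_[:, k]
                assert norm == pytest.approx(1.0, abs=1e-8)

    def test_parameter_validation(self):
        X = np.random.default_rng(0).standard_normal((5, 2))
        with pytest.raises(ValueError):
            GaitKPCA(sigma=-1.0).fit(X)
        with pytest.raises(ValueError):
            GaitKPCA(n_components=6).fit(X)
        with pytest.raises(ValueError):
            GaitKPCA().fit(X[:1])

    def test_rings_separable_in_one_kpca_component(self):
        """The classic nonlinear toy: concentric rings are 1-D separable
        after RBF kernel PCA but not after linear PCA."""
        from sklearn.decomposition import PCA

        rng = np.random.default_rng(7)
        angles = rng.uniform(0, 2 * np.pi, 40)
        radii = np.where(np.arange(40) < 20, 1.0, 3.0)
        X = np.c_[radii * np.cos(angles), radii * np.sin(angles)]
        y = (radii > 2).astype(int)

        z_k = GaitKPCA(sigma=1.0, n_components=1).fit_transform(X).ravel()
        z_p = PCA(n_components=1).fit_transform(X).ravel()

        def best_threshold_accuracy(z):
            accs = [
                max(np.mean((z > thr) == y), np.mean((z <= thr) == y))
                for thr in np.unique(z)
            ]
            return max(accs)

        assert best_threshold_accuracy(z_k) >= 0.95
        assert best_threshold_accuracy(z_p) <= 0.80


class TestTransform:
    def test_training_scores_self_consistent(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((18, 4))
        model = GaitKPCA(sigma=2.0, n_components=5).fit(X)
        scores_fit = center_kernel(
            np.exp(
                -((X[:, None] - X[None]) ** 2).sum(-1) / (2 * model.sigma_**2)
            ),
            "cross",
            row_means=model.row_means_,
            grand_mean=model.grand_mean_,
        ) @ model.alphas_
        np.testing.assert_allclose(model.transform(X), scores_fit, atol=1e-8)

    def test_duplicate_of_training_row(self):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((12, 3))
        model = GaitKPCA(sigma=1.0, n_components=3).fit(X)
        t_all = model.transform(X)
        t_dup = model.transform(X[4:5])
        np.testing.assert_allclose(t_dup[0], t_all[4], atol=1e-10)

    def test_dimension_mismatch(self):
        X = np.random.default_rng(0).standard_normal((8, 3))
        model = GaitKPCA(sigma=1.0).fit(X)
        with pytest.raises(ValueError):
            model.transform(np.zeros((2, 4)))

    def test_score_variance_tracks_eigenvalues(self):
        rng = np.random.default_rng(10)
        X = rng.standard_normal((25, 5))
        model = GaitKPCA(sigma=2.0, n_components=6).fit(X)
        T = model.transform(X)
        emp = T.var(axis=0)  # 1/n normalization
        np.testing.assert_allclose(emp, model.lambdas_ / X.shape[0], atol=1e-6)

    def test_score_columns_orthogonal(self):
        rng = np.random.default_rng(11)
        X = rng.standard_normal((20, 4))
        model = GaitKPCA(sigma=1.5, n_components=5).fit(X)
        T = model.transform(X)
        G = T.T @ T
        off = G - np.diag(np.diag(G))
        assert np.max(np.abs(off)) < 1e-6 * max(1.0, np.max(np.diag(G)))

    def test_linear_kernel_equals_pca_up_to_sign(self):
        from sklearn.decomposition import PCA

        rng = np.random.default_rng(12)
        for _ in range(5):
            X = rng.standard_normal((30, 10))
            p = 4
            T_k = GaitKPCA(kernel="linear", n_components=p).fit_transform(X)
            T_p = PCA(n_components=p).fit_transform(X)
            for k in range(p):
                dev = min(
                    np.max(np.abs(T_k[:, k] - T_p[:, k])),
                    np.max(np.abs(T_k[:, k] + T_p[:, k])),
                )
                assert dev < 1e-6
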