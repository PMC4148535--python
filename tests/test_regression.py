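"""Standardization, subsampling, the neural network, and the exact GP."""

import numpy as np
import pytest

from emgkin.regression import (
    GpModel,
    gp_nll,
    predict_bank,
    predict_gp,
    se_kernel,
    standardize_apply,
    standardize_fit,
    subsample_fixed_interval,
    train_gp,
    train_gp_bank,
    train_nn,
)


class TestStandardize:
    def test_two_point_example(self):
        stats = standardize_fit(np.array([[0.0], [2.0]]))
        assert stats.mean[0] == 1.0 and stats.std[0] == pytest.approx(np.sqrt(2))
        out = standardize_apply(stats, np.array([[0.0], [2.0]]))
        np.testing.assert_allclose(out.ravel(), [-1 / np.sqrt(2), 1 / np.sqrt(2)])

    def test_train_moments_and_test_reuse(self, rng):
        X = rng.normal(3, 2, size=(500, 4))
        stats = standardize_fit(X)
        Z = standardize_apply(stats, X)
        np.testing.assert_allclose(Z.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(Z.var(axis=0, ddof=1), 1.0, atol=1e-10)
        # double application is not the identity
        assert not np.allclose(standardize_apply(stats, Z), Z)

    def test_zero_variance_dimension_dropped_with_warning(self, rng):
        X = np.column_stack([rng.normal(size=50), np.full(50, 7.0)])
        with pytest.warns(UserWarning, match="zero-variance"):
            stats = standardize_fit(X)
        assert standardize_apply(stats, X).shape == (50, 1)


class TestSubsample:
    def test_ceil_arithmetic(self):
        X = np.arange(4800)[:, None]
        Xs, _ = subsample_fixed_interval(X, X, 1200)
        assert Xs.shape[0] == 1200

    def test_identity_when_cap_exceeds_n(self):
        X = np.arange(10)[:, None]
        Xs, _ = subsample_fixed_interval(X, X, 50)
        np.testing.assert_array_equal(Xs, X)

    def test_small_example_rows(self):
        X = np.arange(10)[:, None]
        Xs, _ = subsample_fixed_interval(X, X, 3)
        np.testing.assert_array_equal(Xs.ravel(), [0, 4, 8])


class TestNeuralNetwork:
    def test_learns_realizable_linear_map(self, rng):
        # standardized inputs, targets on the normalized [0, 1] angle scale
        X = rng.normal(size=(600, 4))
        W = 0.1 * rng.normal(size=(4, 3))
        Y = X @ W + 0.5
        model = train_nn(X, Y, hidden_grid=(5, 10), seed=0, max_iter=800)
        assert model.val_mse < 1e-3
        assert set(model.grid_val_mse) == {5, 10}

    def test_constant_targets(self, rng):
        X = rng.normal(size=(300, 2))
        Y = np.full((300, 2), 0.37)
        model = train_nn(X, Y, hidden_grid=(5,), seed=1, max_iter=500)
        # zero-variance targets defeat score-based early stopping, so only
        # approximate recovery of the constant is guaranteed
        assert model.val_mse < 5e-3
        assert np.abs(model.predict(X[:20]) - 0.37).max() < 0.15

    def test_deterministic_given_seed(self, rng):
        X = rng.normal(size=(200, 3))
        Y = X @ rng.normal(size=(3, 2)) + 0.05 * rng.normal(size=(200, 2))
        m1 = train_nn(X, Y, hidden_grid=(8,), seed=42, max_iter=300)
        m2 = train_nn(X, Y, hidden_grid=(8,), seed=42, max_iter=300)
        for w1, w2 in zip(m1.estimator.coefs_, m2.estimator.coefs_):
            np.testing.assert_array_equal(w1, w2)


def brute_force_nll(h, X, y):
    """Dense inverse/determinant evaluation of the marginal likelihood."""
    sf, sn, l = h
    K = sf**2 * np.exp(-((X[:, None, :] - X[None, :, :]) ** 2).sum(-1) / (2 * l**2))
    K = K + sn**2 * np.eye(len(y))
    return float(
        0.5 * y @ np.linalg.inv(K) @ y
        + 0.5 * np.linalg.slogdet(K)[1]
        + 0.5 * len(y) * np.log(2 * np.pi)
    )


class TestGpLikelihood:
    def test_single_point_closed_form(self):
        y, sf, sn, l = 0.7, 1.3, 0.4, 2.0
        s = sf**2 + sn**2
        expected = y**2 / (2 * s) + 0.5 * np.log(s) + 0.5 * np.log(2 * np.pi)
        assert gp_nll((sf, sn, l), np.zeros((1, 2)), np.array([y])) == pytest.approx(
            expected, abs=1e-10)

    def test_matches_brute_force(self, rng):
        for _ in range(25):
            n = rng.integers(2, 20)
            X = rng.normal(size=(n, 3))
            y = rng.normal(size=n)
            h = tuple(rng.uniform(0.2, 2.0, 3))
            assert gp_nll(h, X, y) == pytest.approx(brute_force_nll(h, X, y), abs=1e-8)

    def test_duplicated_point_changes_nll(self, rng):
        X = rng.normal(size=(5, 2))
        y = rng.normal(size=5)
        h = (1.0, 0.3, 1.0)
        a = gp_nll(h, X, y)
        b = gp_nll(h, np.vstack([X, X[:1]]), np.append(y, y[0]))
        assert a != pytest.approx(b, abs=1e-6)


class TestGpTraining:
    def test_hyperparameter_recovery(self, rng):
        true = (1.5, 0.2, 1.0)
        X = rng.uniform(-3, 3, size=(400, 2))
        K = se_kernel(X, X, true[0], true[2]) + true[1] ** 2 * np.eye(400)
        y = rng.multivariate_normal(np.zeros(400), K)
        model = train_gp(X, y, restarts=3, seed=0)
        learned = np.log([model.sigma_f, model.sigma_n, model.length])
        np.testing.assert_allclose(learned, np.log(true), atol=0.3)

    def test_pure_noise_shrinks_signal(self, rng):
        X = rng.normal(size=(150, 2))
        y = rng.normal(size=150)
        model = train_gp(X, y, restarts=2, seed=1)
        assert model.sigma_f < 0.5 * model.sigma_n

    def test_deterministic_given_seed(self, rng):
        X = rng.normal(size=(60, 2))
        y = np.sin(X[:, 0]) + 0.1 * rng.normal(size=60)
        m1 = train_gp(X, y, restarts=2, seed=5)
        m2 = train_gp(X, y, restarts=2, seed=5)
        assert (m1.sigma_f, m1.sigma_n, m1.length) == (m2.sigma_f, m2.sigma_n, m2.length)


class TestGpPrediction:
    def test_interpolates_with_tiny_noise(self, rng):
        X = rng.uniform(-2, 2, size=(20, 1))
        y = np.sin(X[:, 0])
        model = GpModel(1.0, 1e-8, 1.0, X, y)
        mean, _ = predict_gp(model, X)
        np.testing.assert_allclose(mean, y, atol=1e-5)

    def test_reverts_to_prior_far_away(self, rng):
        X = rng.normal(size=(30, 2))
        y = rng.normal(size=30)
        model = GpModel(1.2, 0.3, 0.5, X, y)
        mean, varr = predict_gp(model, np.full((1, 2), 50.0))
        assert abs(mean[0]) < 1e-6
        assert varr[0] == pytest.approx(1.2**2 + 0.3**2, rel=1e-6)

    def test_matches_dense_solve_oracle(self, rng):
        for _ in range(25):
            n = rng.integers(3, 30)
            X = rng.normal(size=(n, 2))
            y = rng.normal(size=n)
            sf, sn, l = rng.uniform(0.3, 2.0, 3)
            model = GpModel(sf, sn, l, X, y)
            Xs = rng.normal(size=(7, 2))
            mean, _ = predict_gp(model, Xs)
            K = se_kernel(X, X, sf, l) + sn**2 * np.eye(n)
            oracle = se_kernel(Xs, X, sf, l) @ np.linalg.solve(K, y)
            np.testing.assert_allclose(mean, oracle, atol=1e-8)

    def test_dimension_mismatch_rejected(self, rng):
        model = GpModel(1.0, 0.1, 1.0, rng.normal(size=(10, 3)), rng.normal(size=10))
        with pytest.raises(ValueError):
            predict_gp(model, rng.normal(size=(4, 2)))

    def test_agrees_with_sklearn_reference(self, rng):
        # independent cross-check against an established GP implementation
        from sklearn.gaussian_process import GaussianProcessRegressor
        from sklearn.gaussian_process.kernels import RBF, WhiteKernel, ConstantKernel

        X = rng.normal(size=(40, 2))
        y = np.sin(X[:, 0]) * np.cos(X[:, 1])
        sf, sn, l = 1.1, 0.15, 0.8
        mean, _ = predict_gp(GpModel(sf, sn, l, X, y), X[:10] + 0.1)
        gpr = GaussianProcessRegressor(
            kernel=ConstantKernel(sf**2, "fixed") * RBF(l, "fixed")
            + WhiteKernel(sn**2, "fixed"),
            alpha=0.0, optimizer=None,
        ).fit(X, y)
        np.testing.assert_allclose(mean, gpr.predict(X[:10] + 0.1), atol=1e-6)


class TestGpBank:
    def test_bank_shapes_and_linear_map(self, rng):
        X = rng.uniform(0, 1, size=(300, 3))
        W = rng.normal(size=(3, 4))
        Y = X @ W
        bank = train_gp_bank(X, Y, max_n=150, restarts=1, seed=0)
        pred = predict_bank(bank, X[:50])
        assert pred.shape == (50, 4)
        for j in range(4):
            r = np.corrcoef(pred[:, j], Y[:50, j])[0, 1]
            assert r >= 0.95

    def test_identical_targets_give_identical_models(self, rng):
        X = rng.normal(size=(80, 2))
        y = np.sin(X[:, 0])
        Y = np.column_stack([y, y])
        bank = train_gp_bank(X, Y, max_n=80, restarts=1, seed=0)
        # same data, same restart seed offset differs; compare predictions
        p = predict_bank(bank, X[:10])
        np.testing.assert_allclose(p[:, 0], p[:, 1], atol=1e-6)
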