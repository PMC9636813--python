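import numpy as np
import pytest

from phytomarker.errors import ConfigError, FitError
from phytomarker.pls import (cross_validate_q2, fit_pls, permutation_test,
                             select_components, standardized_coefficients,
                             vip_scores)


def _random_instance(seed, n=20, p=6, noise=0.3):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    beta = rng.standard_normal(p)
    y = X @ beta + noise * rng.standard_normal(n)
    return X, y


def _ols_predictions(X, y):
    Z = np.column_stack([np.ones(len(y)), X])
    coef, *_ = np.linalg.lstsq(Z, y, rcond=None)
    return Z @ coef


class TestFit:
    def test_single_proportional_column_is_explained_by_one_component(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((15, 4))
        model = fit_pls(X, 3.0 * X[:, 2], min(14, 4))
        assert model.r2y_cum == pytest.approx(1.0, abs=1e-10)

    def test_full_rank_model_reproduces_ols_training_predictions(self):
        for seed in range(5):
            X, y = _random_instance(seed, n=20, p=5)
            model = fit_pls(X, y, 5)
            np.testing.assert_allclose(model.predict(X), _ols_predictions(X, y),
                                       atol=1e-8)

    def test_matches_reference_pls_implementation(self):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        X, y = _random_instance(11, n=20, p=6)
        for A in (1, 2, 3):
            model = fit_pls(X, y, A)
            ref = sklearn.PLSRegression(n_components=A, scale=True).fit(
                X, y.reshape(-1, 1))
            np.testing.assert_allclose(
                model.predict(X), ref.predict(X).ravel(), atol=1e-6)

    def test_scores_are_mutually_orthogonal(self):
        X, y = _random_instance(3, n=25, p=8)
        T = fit_pls(X, y, 5).scores
        gram = T.T @ T
        off = gram - np.diag(np.diag(gram))
        assert np.max(np.abs(off)) < 1e-8

    def test_zero_variance_column_named_in_error(self):
        X, y = _random_instance(1, n=10, p=3)
        X[:, 1] = 7.0
        with pytest.raises(FitError, match="c2"):
            fit_pls(X, y, 2, feature_names=["c1", "c2", "c3"])

    def test_dimension_preconditions(self):
        X, y = _random_instance(2, n=10, p=4)
        with pytest.raises(ConfigError):
            fit_pls(X, y, 10)
        with pytest.raises(ConfigError):
            fit_pls(X[:2], y[:2], 1)


class TestVIP:
    def test_single_predictor_has_unit_vip(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((12, 1))
        model = fit_pls(X, X[:, 0] + 0.1 * rng.standard_normal(12), 1)
        assert model.vip[0] == pytest.approx(1.0, abs=1e-10)

    def test_mean_square_vip_is_one(self):
        for seed in range(20):
            X, y = _random_instance(seed, n=15, p=7)
            model = fit_pls(X, y, 3)
            assert np.mean(model.vip ** 2) == pytest.approx(1.0, abs=1e-8)
            np.testing.assert_allclose(vip_scores(model), model.vip, atol=1e-12)

    def test_driving_variable_has_max_vip_above_one(self):
        rng = np.random.default_rng(9)
        n, p = 40, 6
        X = rng.standard_normal((n, p))
        model = fit_pls(X, X[:, 0], 1)
        assert np.argmax(model.vip) == 0
        assert model.vip[0] > 1.0


class TestCoefficients:
    def test_identity_on_single_exact_predictor(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(10)
        model = fit_pls(x.reshape(-1, 1), x, 1)
        assert model.coefficients[0] == pytest.approx(1.0, abs=1e-10)

    def test_sign_flip_equivariance(self):
        X, y = _random_instance(6, n=15, p=4)
        base = fit_pls(X, y, 2).coefficients
        Xf = X.copy()
        Xf[:, 1] *= -1.0
        flipped = fit_pls(Xf, y, 2).coefficients
        np.testing.assert_allclose(flipped[1], -base[1], atol=1e-10)
        np.testing.assert_allclose(np.delete(flipped, 1), np.delete(base, 1),
                                   atol=1e-10)

    def test_full_rank_equals_standardized_ols(self):
        X, y = _random_instance(8, n=30, p=5)
        model = fit_pls(X, y, 5)
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        ys = (y - y.mean()) / y.std(ddof=1)
        ols = np.linalg.lstsq(Z, ys, rcond=None)[0]
        np.testing.assert_allclose(standardized_coefficients(model), ols,
                                   atol=1e-6)


class TestCrossValidation:
    def test_pure_noise_has_no_predictivity(self):
        q2_first = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((100, 5))
            y = rng.standard_normal(100)
            q2_first.append(cross_validate_q2(X, y, 1, seed=seed)[0])
        assert np.median(q2_first) <= 0.1

    def test_noiseless_single_factor_signal_is_predictive(self):
        rng = np.random.default_rng(17)
        f = rng.standard_normal(60)
        loadings = rng.uniform(0.5, 1.5, 5)
        X = np.outer(f, loadings) + 0.01 * rng.standard_normal((60, 5))
        assert cross_validate_q2(X, f, 1, seed=0)[0] >= 0.95

    def test_leave_one_out_matches_brute_force_press(self):
        """LOO Q² against a naive per-fold single-component PLS1 oracle."""
        rng = np.random.default_rng(2)
        X = rng.standard_normal((5, 3))
        y = rng.standard_normal(5)
        press = 0.0
        for i in range(5):
            tr = np.delete(np.arange(5), i)
            Xt, yt = X[tr], y[tr]
            xm, xs = Xt.mean(0), Xt.std(0, ddof=1)
            ym, ys = yt.mean(), yt.std(ddof=1)
            Z, v = (Xt - xm) / xs, (yt - ym) / ys
            w = Z.T @ v
            w /= np.linalg.norm(w)
            t = Z @ w
            q = (v @ t) / (t @ t)
            b = w * q  # single component: P'W = ||t||-scaled identity piece
            p_load = Z.T @ t / (t @ t)
            b = w * (q / (p_load @ w))
            pred = ym + ys * (((X[i] - xm) / xs) @ b)
            press += (y[i] - pred) ** 2
        expected = 1.0 - press / np.sum((y - y.mean()) ** 2)
        got = cross_validate_q2(X, y, 1, folds=5, seed=0)[0]
        assert got == pytest.approx(expected, abs=1e-10)

    def test_q2_never_exceeds_training_r2(self):
        for seed in range(10):
            X, y = _random_instance(seed, n=24, p=6, noise=0.5)
            q2 = cross_validate_q2(X, y, 3, seed=seed)
            for A in (1, 2, 3):
                model = fit_pls(X, y, A)
                assert q2[A - 1] <= model.r2y_cum + 1e-10

    def test_fold_bounds(self):
        X, y = _random_instance(0, n=10, p=3)
        with pytest.raises(ConfigError):
            cross_validate_q2(X, y, 1, folds=1)
        with pytest.raises(ConfigError):
            cross_validate_q2(X, y, 1, folds=11)


class TestSelection:
    @pytest.mark.parametrize("q2,expected", [
        ((0.4, 0.7, 0.71, 0.70), 2),
        ((0.1, 0.2, 0.5, 0.8), 4),
    ])
    def test_max_q2_rule(self, q2, expected):
        assert select_components(np.array(q2)) == expected

    def test_gain_threshold_rule(self):
        assert select_components(np.array([0.4, 0.48, 0.50]),
                                 rule="gain_threshold") == 2

    def test_all_negative_warns_and_returns_one(self):
        with pytest.warns(UserWarning, match="no predictive component"):
            assert select_components(np.array([-0.2, -0.1])) == 1


class TestPermutation:
    def test_deterministic_given_seed(self):
        X, y = _random_instance(3, n=20, p=5)
        r1 = permutation_test(X, y, 1, n_permutations=20, seed=42)
        r2 = permutation_test(X, y, 1, n_permutations=20, seed=42)
        np.testing.assert_array_equal(r1.permuted_q2, r2.permuted_q2)
        assert r1.empirical_p_q2 == r2.empirical_p_q2

    def test_strong_signal_is_significant(self):
        X, y = _random_instance(10, n=31, p=10, noise=0.2)
        res = permutation_test(X, y, 2, n_permutations=199, seed=0)
        assert res.empirical_p_q2 <= 0.05
        assert res.observed_q2 > max(res.permuted_q2)

    def test_p_value_floor(self):
        X, y = _random_instance(1, n=20, p=4, noise=0.1)
        res = permutation_test(X, y, 1, n_permutations=49, seed=1)
        assert res.empirical_p_q2 >= 1.0 / 50.0

    def test_constant_response_rejected(self):
        X, _ = _random_instance(0)
        with pytest.raises(FitError):
            permutation_test(X, np.ones(20), 1, n_permutations=20, seed=0)

    def test_minimum_permutations_enforced(self):
        X, y = _random_instance(0)
        with pytest.raises(ConfigError):
            permutation_test(X, y, 1, n_permutations=5, seed=0)
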