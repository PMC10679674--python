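import numpy as np
import pytest

from cottonvit import ModelSpec, evaluate, fit_plsr, fit_svr, make_model


def _nipals_pls1(X, y, n_components):
    """Independent autoscaled PLS1 (NIPALS) returning the coefficient
    vector on the original scale."""
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    x_mean, x_sd = X.mean(0), X.std(0, ddof=1)
    x_sd[x_sd == 0] = 1.0
    y_mean, y_sd = y.mean(), y.std(ddof=1)
    E = (X - x_mean) / x_sd
    f = (y - y_mean) / y_sd
    W, P, Q = [], [], []
    for _ in range(n_components):
        w = E.T @ f
        w /= np.linalg.norm(w)
        t = E @ w
        p = E.T @ t / (t @ t)
        q = f @ t / (t @ t)
        E = E - np.outer(t, p)
        f = f - q * t
        W.append(w), P.append(p), Q.append(q)
    W, P, Q = np.array(W).T, np.array(P).T, np.array(Q)
    beta_scaled = W @ np.linalg.solve(P.T @ W, Q)
    return beta_scaled / x_sd * y_sd


class TestEvaluate:
    def test_perfect_prediction(self):
        class Identity:
            def predict(self, X):
                return X.ravel()
        r, rmse = evaluate(Identity(), np.array([[1.0], [2.0], [4.0]]),
                           [1.0, 2.0, 4.0])
        assert (r, rmse) == (pytest.approx(1.0), pytest.approx(0.0))

    def test_hand_rmse(self):
        class Fixed:
            def predict(self, X):
                return np.array([2.0, 4.0])
        r, rmse = evaluate(Fixed(), np.zeros((2, 1)), [1.0, 5.0])
        assert rmse == pytest.approx(1.0)  # sqrt((1 + 1)/2)

    def test_matches_textbook_formulas(self, rng):
        pred = rng.normal(size=50)
        y = rng.normal(size=50)
        class Fixed:
            def predict(self, X):
                return pred
        r, rmse = evaluate(Fixed(), np.zeros((50, 1)), y)
        sp, sy = pred - pred.mean(), y - y.mean()
        r_direct = (sp @ sy) / np.sqrt((sp @ sp) * (sy @ sy))
        assert r == pytest.approx(r_direct, abs=1e-12)
        assert rmse == pytest.approx(np.sqrt(np.sum((pred - y) ** 2) / 50), abs=1e-12)

    def test_order_invariance(self, rng):
        X = rng.normal(size=(30, 4))
        y = X @ rng.normal(size=4) + 0.1 * rng.normal(size=30)
        model = fit_plsr(X, y)
        perm = rng.permutation(30)
        assert evaluate(model, X, y) == pytest.approx(evaluate(model, X[perm], y[perm]))

    def test_zero_variance_rejected(self):
        class Flat:
            def predict(self, X):
                return np.zeros(len(X))
        with pytest.raises(ValueError, match="variance"):
            evaluate(Flat(), np.zeros((5, 1)), np.arange(5.0))


class TestPLSR:
    def test_one_component_univariate_equals_ols(self, rng):
        x = rng.normal(size=25)
        y = 2.0 * x + 1.0 + 0.1 * rng.normal(size=25)
        model = fit_plsr(x[:, None], y, ModelSpec(kind="PLSR", plsr_components=1))
        slope, intercept = np.polyfit(x, y, 1)
        np.testing.assert_allclose(model.predict(x[:, None]),
                                   slope * x + intercept, atol=1e-8)

    def test_exact_three_dim_latent_recovered(self, rng):
        T = rng.normal(size=(40, 3))
        X = T @ rng.normal(size=(3, 12))
        X += 1e-9 * rng.normal(size=X.shape)  # break exact collinearity
        y = T @ np.array([1.0, -2.0, 0.5])
        model = fit_plsr(X, y, ModelSpec(kind="PLSR", plsr_components=3))
        r, _ = evaluate(model, X, y)
        assert r == pytest.approx(1.0, abs=1e-6)

    def test_coefficients_match_nipals_oracle(self, rng):
        X = rng.normal(size=(6, 4))
        y = rng.normal(size=6)
        model = fit_plsr(X, y, ModelSpec(kind="PLSR", plsr_components=2))
        np.testing.assert_allclose(model.coef_, _nipals_pls1(X, y, 2), atol=1e-8)

    def test_full_rank_components_reproduce_least_squares(self, rng):
        X = rng.normal(size=(30, 5))
        y = rng.normal(size=30)
        model = fit_plsr(X, y, ModelSpec(kind="PLSR", plsr_components=5))
        A = np.column_stack([np.ones(30), X])
        beta = np.linalg.lstsq(A, y, rcond=None)[0]
        np.testing.assert_allclose(model.predict(X), A @ beta, atol=1e-6)

    def test_too_many_components_rejected(self, rng):
        with pytest.raises(ValueError, match="components"):
            fit_plsr(rng.normal(size=(4, 2)), rng.normal(size=4),
                     ModelSpec(kind="PLSR", plsr_components=3))


class TestSVR:
    def test_constant_target_within_epsilon(self, rng):
        X = rng.normal(size=(20, 3))
        y = np.full(20, 5.0)
        model = fit_svr(X, y)
        assert np.all(np.abs(model.predict(X) - 5.0) <= 0.1 + 1e-9)

    def test_huge_epsilon_gives_flat_solution(self, rng):
        X = rng.normal(size=(20, 3))
        y = rng.normal(size=20)
        model = fit_svr(X, y, ModelSpec(kind="SVR", svr_epsilon=100.0))
        assert np.ptp(model.predict(X)) <= 1e-6

    def test_rbf_beats_linear_on_quadratic_data(self, rng):
        x = np.linspace(-2, 2, 40)
        y = x ** 2 + 0.05 * rng.normal(size=40)
        x_test = np.linspace(-1.9, 1.9, 21)
        y_test = x_test ** 2
        model = fit_svr(x[:, None], y)
        svr_rmse = np.sqrt(np.mean((model.predict(x_test[:, None]) - y_test) ** 2))
        slope, intercept = np.polyfit(x, y, 1)
        ols_rmse = np.sqrt(np.mean((slope * x_test + intercept - y_test) ** 2))
        assert svr_rmse < ols_rmse


class TestSpecValidation:
    def test_unknown_kind(self):
        with pytest.raises(ValueError, match="kind"):
            make_model(ModelSpec(kind="MLP"))

    def test_models_beat_mean_baseline(self, rng):
        X = rng.normal(size=(60, 8))
        y = X[:, 0] - X[:, 3] + 0.2 * rng.normal(size=60)
        Xt, yt = X[:40], y[:40]
        Xe, ye = X[40:], y[40:]
        baseline = np.sqrt(np.mean((ye - yt.mean()) ** 2))
        for kind in ("PLSR", "SVR", "CNN"):
            spec = ModelSpec(kind=kind, cnn_epochs=150, cnn_lr=1e-2, rng_seed=0)
            model = make_model(spec).fit(Xt, yt)
            _, rmse = evaluate(model, Xe, ye)
            assert rmse < baseline, kind
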