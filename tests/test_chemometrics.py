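"""PLSR and linear SVR calibration: algorithmic oracles and CV mechanics."""

import numpy as np
import pytest

import leafspec as ls
from leafspec.chemometrics import (
    CVSpec,
    _dcd_svr,
    _nipals,
    cv_folds,
    cross_validate,
    svr_dual_objective,
)
from leafspec.preprocess import Standardizer


class TestCvFolds:
    def test_leave_one_out_when_k_equals_n(self):
        folds = cv_folds(10, CVSpec(k=10, seed=0))
        assert len(folds) == 10
        assert all(f.size == 1 for f in folds)

    def test_balanced_partition_sizes(self):
        folds = cv_folds(23, CVSpec(k=10, seed=1))
        sizes = sorted((f.size for f in folds), reverse=True)
        assert sizes == [3, 3, 3, 2, 2, 2, 2, 2, 2, 2]
        assert sorted(np.concatenate(folds).tolist()) == list(range(23))

    def test_seeded_reproducibility(self):
        a = cv_folds(30, CVSpec(k=5, seed=42))
        b = cv_folds(30, CVSpec(k=5, seed=42))
        assert all(np.array_equal(x, y) for x, y in zip(a, b))

    def test_k_above_n_rejected(self):
        with pytest.raises(ValueError):
            cv_folds(5, CVSpec(k=10, seed=0))


class TestCrossValidate:
    def test_perfect_model_has_zero_rmse(self, rng):
        X = rng.normal(size=(20, 3))
        y = X @ np.array([1.0, -2.0, 0.5])

        def fit_predict(X_tr, y_tr, X_te):
            coef, *_ = np.linalg.lstsq(X_tr, y_tr, rcond=None)
            return (X_te @ coef).reshape(-1, 1)

        out = cross_validate(fit_predict, X, y, CVSpec(k=5, seed=3))
        assert out[0] == pytest.approx(0.0, abs=1e-10)

    def test_pooled_rmse_matches_manual_two_fold_computation(self, rng):
        X = rng.normal(size=(8, 2))
        y = rng.normal(size=8)

        def fit_predict(X_tr, y_tr, X_te):
            return np.full((len(X_te), 1), y_tr.mean())

        cv = CVSpec(k=2, seed=9)
        out = cross_validate(fit_predict, X, y, cv)
        folds = cv_folds(8, cv)
        sq = 0.0
        for fold in folds:
            mask = np.ones(8, bool)
            mask[fold] = False
            sq += np.sum((y[mask].mean() - y[fold]) ** 2)
        assert out[0] == pytest.approx(np.sqrt(sq / 8), abs=1e-12)


class TestPLSR:
    def test_univariate_exact_fit(self, rng):
        x = rng.uniform(1.0, 5.0, 30).reshape(-1, 1)
        y = 2.0 * x.ravel()
        res = ls.fit_plsr(x, y, max_lv=1, cv=CVSpec(k=5, seed=0))
        assert np.allclose(res.predict(x), y, atol=1e-10)

    def test_full_rank_plsr_equals_ols_oracle(self, rng):
        n, p = 60, 5
        X = rng.normal(size=(n, p))
        beta = np.array([1.0, -0.5, 2.0, 0.0, 0.7])
        y = X @ beta + 3.0
        res = ls.fit_plsr(X, y, max_lv=p, cv=CVSpec(k=10, seed=1))
        # normal-equations oracle on the same data
        A = np.column_stack([np.ones(n), X])
        coef = np.linalg.solve(A.T @ A, A.T @ y)
        yhat_ols = A @ coef
        yhat_pls = res.predict(X, n_lv=p)
        assert np.allclose(yhat_pls, yhat_ols, atol=1e-8)

    def test_scores_orthogonal_and_weights_unit_norm(self, rng):
        X = rng.normal(size=(40, 12))
        y = rng.normal(size=40)
        xs, ys = Standardizer.fit(X), Standardizer.fit(y.reshape(-1, 1))
        W, P, q, T = _nipals(xs.apply(X), ys.apply(y.reshape(-1, 1)).ravel(), 6)
        G = T.T @ T
        off = G - np.diag(np.diag(G))
        assert np.max(np.abs(off)) < 1e-8
        assert np.allclose(np.linalg.norm(W, axis=0), 1.0, atol=1e-10)

    def test_training_r2_nondecreasing_in_lv(self, rng):
        X = rng.normal(size=(50, 10))
        y = rng.normal(size=50)
        res = ls.fit_plsr(X, y, max_lv=8, cv=CVSpec(k=5, seed=2))
        r2s = [ls.r_squared(y, res.predict(X, n_lv=a), definition="ss")
               for a in range(1, 9)]
        assert all(b >= a - 1e-10 for a, b in zip(r2s, r2s[1:]))

    def test_three_factor_simulation_selects_sensible_lv_count(self):
        rng = np.random.default_rng(11)
        n, p = 120, 40
        scores = rng.normal(size=(n, 3))
        loadings = rng.normal(size=(3, p))
        X = scores @ loadings + 0.05 * rng.normal(size=(n, p))
        y = scores @ np.array([1.0, -1.0, 0.5]) + 0.1 * rng.normal(size=n)
        train, test = np.arange(0, 80), np.arange(80, n)
        res = ls.fit_plsr(X[train], y[train], max_lv=10, cv=CVSpec(k=10, seed=3))
        assert 2 <= res.selected_n_lv <= 6
        r2_sel = ls.r_squared(y[test], res.predict(X[test]))
        r2_3lv = ls.r_squared(y[test], res.predict(X[test], n_lv=3))
        assert r2_sel >= r2_3lv - 0.05

    def test_prediction_at_training_mean_is_training_y_mean(self, rng):
        X = rng.normal(size=(30, 6))
        y = rng.normal(size=30)
        res = ls.fit_plsr(X, y, max_lv=3, cv=CVSpec(k=5, seed=4))
        pred = res.predict(X.mean(axis=0).reshape(1, -1))
        assert pred[0] == pytest.approx(y.mean(), abs=1e-10)

    def test_batch_prediction_equals_looped(self, rng):
        X = rng.normal(size=(25, 5))
        y = rng.normal(size=25)
        res = ls.fit_plsr(X, y, max_lv=3, cv=CVSpec(k=5, seed=5))
        Xn = rng.normal(size=(7, 5))
        batch = res.predict(Xn)
        looped = np.array([res.predict(row.reshape(1, -1))[0] for row in Xn])
        assert np.allclose(batch, looped, atol=1e-12)

    def test_zero_variance_response_rejected(self, rng):
        X = rng.normal(size=(20, 4))
        with pytest.raises(ValueError, match="variance"):
            ls.fit_plsr(X, np.full(20, 2.0), max_lv=2, cv=CVSpec(k=5, seed=0))

    def test_max_lv_clipped_with_warning(self, rng):
        X = rng.normal(size=(20, 30))
        y = rng.normal(size=20)
        with pytest.warns(UserWarning, match="clipping"):
            res = ls.fit_plsr(X, y, max_lv=25, cv=CVSpec(k=5, seed=0))
        assert res.coef_by_lv.shape[1] <= 15

    def test_matches_sklearn_cross_check(self, rng):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        X = rng.normal(size=(40, 15))
        y = rng.normal(size=40)
        res = ls.fit_plsr(X, y, max_lv=5, cv=CVSpec(k=5, seed=6))
        ref = sklearn.PLSRegression(n_components=5, scale=True).fit(X, y)
        assert np.allclose(res.predict(X, n_lv=5), ref.predict(X).ravel(), atol=1e-6)


class TestSVR:
    def test_exact_linear_response_has_residuals_within_epsilon(self, rng):
        X = rng.normal(size=(40, 5))
        y = X @ np.array([1.0, 2.0, -1.0, 0.5, 0.0]) + 4.0
        res = ls.fit_svr(X, y, c_grid=[100.0], epsilon=0.1, cv=CVSpec(k=5, seed=0))
        z_resid = res.y_standardizer.apply(y.reshape(-1, 1)).ravel() - \
            res.x_standardizer.apply(X) @ res.coefficient_vector
        assert np.max(np.abs(z_resid)) <= 0.1 + 1e-6

    def test_constant_response_gives_zero_coefficients(self, rng):
        X = rng.normal(size=(20, 4))
        res = ls.fit_svr(X, np.full(20, 5.0), cv=CVSpec(k=5, seed=0))
        assert np.allclose(res.coefficient_vector, 0.0)
        assert res.intercept == 0.0
        assert np.allclose(res.predict(X), 5.0)
        # all C values tie at RMSE_CV 0; the smallest C wins
        assert res.C == 0.01

    def test_dual_objective_matches_generic_qp_oracle(self, rng):
        from scipy.optimize import minimize

        n, p = 30, 4
        X = rng.normal(size=(n, p))
        y = X @ rng.normal(size=p) + 0.3 * rng.normal(size=n)
        xs, ys = Standardizer.fit(X), Standardizer.fit(y.reshape(-1, 1))
        Z = xs.apply(X)
        zy = ys.apply(y.reshape(-1, 1)).ravel()
        C, eps = 1.0, 0.1
        w, beta, conv, _ = _dcd_svr(Z, zy, C, eps, tol=1e-10)
        assert conv
        ours = svr_dual_objective(Z, zy, beta, eps)

        # independent oracle: smooth box-constrained QP on the split
        # parametrisation beta = a_plus - a_minus, a± in [0, C]
        Q = Z @ Z.T

        def obj(x):
            ap, am = x[:n], x[n:]
            b = ap - am
            Qb = Q @ b
            return 0.5 * b @ Qb - zy @ b + eps * np.sum(ap + am)

        def grad(x):
            ap, am = x[:n], x[n:]
            Qb = Q @ (ap - am)
            return np.concatenate([Qb - zy + eps, -(Qb - zy) + eps])

        x0 = np.zeros(2 * n)
        sol = minimize(obj, x0, jac=grad, method="L-BFGS-B",
                       bounds=[(0.0, C)] * (2 * n),
                       options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-10})
        oracle = sol.fun
        scale = max(abs(oracle), 1e-8)
        assert abs(ours - oracle) / scale < 1e-4

    def test_kkt_complementarity_at_solution(self, rng):
        n, p = 30, 4
        X = rng.normal(size=(n, p))
        y = X @ rng.normal(size=p) + 0.3 * rng.normal(size=n)
        xs, ys = Standardizer.fit(X), Standardizer.fit(y.reshape(-1, 1))
        Z, zy = xs.apply(X), ys.apply(y.reshape(-1, 1)).ravel()
        C, eps, tol = 1.0, 0.1, 1e-5
        w, beta, conv, _ = _dcd_svr(Z, zy, C, eps, tol=1e-10)
        resid = zy - Z @ w
        for b, r in zip(beta, resid):
            if abs(b) < tol:  # inactive: residual inside the tube
                assert abs(r) <= eps + 1e-3
            elif abs(b) < C - tol:  # free: residual on the tube boundary
                assert abs(abs(r) - eps) <= 1e-3
            else:  # at bound: residual outside the tube, sign matches beta
                assert abs(r) >= eps - 1e-3
                assert np.sign(r) == np.sign(b)

    def test_dual_objective_not_worse_than_zero_start(self, rng):
        X = rng.normal(size=(25, 3))
        y = rng.normal(size=25)
        xs, ys = Standardizer.fit(X), Standardizer.fit(y.reshape(-1, 1))
        Z, zy = xs.apply(X), ys.apply(y.reshape(-1, 1)).ravel()
        _, beta, _, _ = _dcd_svr(Z, zy, 1.0, 0.1)
        assert svr_dual_objective(Z, zy, beta, 0.1) <= 0.0  # objective at beta=0

    def test_non_positive_c_rejected(self, rng):
        X = rng.normal(size=(20, 3))
        y = rng.normal(size=20)
        with pytest.raises(ValueError, match="positive"):
            ls.fit_svr(X, y, c_grid=[0.0, 1.0], cv=CVSpec(k=5, seed=0))

    def test_batch_prediction_equals_looped(self, rng):
        X = rng.normal(size=(25, 4))
        y = rng.normal(size=25)
        res = ls.fit_svr(X, y, c_grid=[1.0], cv=CVSpec(k=5, seed=1))
        Xn = rng.normal(size=(6, 4))
        batch = res.predict(Xn)
        looped = np.array([res.predict(row.reshape(1, -1))[0] for row in Xn])
        assert np.allclose(batch, looped, atol=1e-12)

    def test_default_c_grid_has_five_decades(self):
        assert list(ls.chemometrics.DEFAULT_C_GRID) == [0.01, 0.1, 1.0, 10.0, 100.0]
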