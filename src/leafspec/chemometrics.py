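"""Whole-spectrum calibration models.

Two calibration families, both fitted in standardized space (predictors and
response zero-centered and scaled to unit sample variance) with hyperparameters
chosen by k-fold random-segment cross-validation:

* :class:`PLSCalibration` — partial least squares regression computed by
  NIPALS with X (and y) deflation, considering up to ``max_lv`` latent
  variables and selecting the count with the lowest cross-validated RMSE.
* :class:`SVRCalibration` — linear epsilon-insensitive support vector
  regression solved by dual coordinate descent, selecting the cost C from a
  grid (default 0.01, 0.1, 1, 10, 100) by the same criterion.

Both follow the model/results idiom: construct the model with its data, call
``fit()``, and read estimates, CV diagnostics and ``summary()`` off the
returned results object. RMSE_CV is pooled over all held-out residuals and is
reported in original trait units; the standardizers are refitted on each
fold-complement so no held-out statistic leaks into scaling.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .preprocess import Standardizer

__all__ = [
    "CVSpec",
    "cv_folds",
    "cross_validate",
    "PLSCalibration",
    "PLSResults",
    "SVRCalibration",
    "SVRResults",
    "fit_plsr",
    "fit_svr",
]

DEFAULT_C_GRID = (0.01, 0.1, 1.0, 10.0, 100.0)


@dataclass
class CVSpec:
    """Random-segment k-fold specification (near-equal fold sizes)."""

    k: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("cross-validation needs k >= 2")


def cv_folds(n: int, cv: CVSpec) -> list[np.ndarray]:
    """Partition indices 0..n-1 into k seeded random segments, sizes differ <= 1."""
    if cv.k > n:
        raise ValueError(f"k={cv.k} folds but only n={n} samples")
    perm = np.random.default_rng(cv.seed).permutation(n)
    return [np.sort(f) for f in np.array_split(perm, cv.k)]


def cross_validate(fit_predict, X: np.ndarray, y: np.ndarray, cv: CVSpec) -> np.ndarray:
    """Pooled cross-validated RMSE per hyperparameter value.

    ``fit_predict(X_train, y_train, X_test)`` must return an
    (n_test, n_hyper) array of predictions in original trait units. The
    return value is sqrt(mean over all held-out squared errors) per
    hyperparameter, i.e. residuals are pooled across folds, not averaged
    per fold.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    folds = cv_folds(len(y), cv)
    sq_sums = None
    for fold in folds:
        mask = np.ones(len(y), dtype=bool)
        mask[fold] = False
        preds = np.atleast_2d(fit_predict(X[mask], y[mask], X[fold]))
        if preds.shape[0] != fold.size:
            preds = preds.T
        errs = (preds - y[fold, None]) ** 2
        sq_sums = errs.sum(axis=0) if sq_sums is None else sq_sums + errs.sum(axis=0)
    return np.sqrt(sq_sums / len(y))


# ---------------------------------------------------------------------------
# NIPALS partial least squares
# ---------------------------------------------------------------------------

def _nipals(X: np.ndarray, y: np.ndarray, max_lv: int):
    """NIPALS PLS1 with X and y deflation on standardized data.

    Returns (W, P, q, T): x-weights (p, A), x-loadings (p, A), y-loadings
    (A,), and training scores (n, A). A may fall below max_lv if the residual
    collapses (rank exhausted).
    """
    Xd = X.copy()
    yd = y.copy()
    n, p = X.shape
    W = np.zeros((p, max_lv))
    P = np.zeros((p, max_lv))
    q = np.zeros(max_lv)
    T = np.zeros((n, max_lv))
    a = 0
    for a in range(max_lv):
        w = Xd.T @ yd
        nw = np.linalg.norm(w)
        if nw < 1e-12:
            break
        w /= nw
        t = Xd @ w
        tt = float(t @ t)
        if tt < 1e-12:
            break
        W[:, a] = w
        T[:, a] = t
        P[:, a] = Xd.T @ t / tt
        q[a] = float(yd @ t) / tt
        Xd -= np.outer(t, P[:, a])
        yd = yd - q[a] * t
    else:
        a = max_lv
    return W[:, :a], P[:, :a], q[:a], T[:, :a]


def _coefficients_by_lv(W: np.ndarray, P: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Standardized-space regression vectors B[:, a-1] for each component count a.

    B_a = W_a (P_a^T W_a)^{-1} q_a — the usual NIPALS back-transformation of
    latent-space loadings to original predictors.
    """
    p, A = W.shape
    B = np.zeros((p, A))
    PtW = P.T @ W
    for a in range(1, A + 1):
        coef_latent = np.linalg.solve(PtW[:a, :a], q[:a])
        B[:, a - 1] = W[:, :a] @ coef_latent
    return B


@dataclass
class PLSResults:
    """Fitted PLS calibration: scaling statistics, loadings, CV curve."""

    x_standardizer: Standardizer
    y_standardizer: Standardizer
    weights: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    scores: np.ndarray
    coef_by_lv: np.ndarray = field(repr=False)
    selected_n_lv: int = 1
    rmse_cv_by_lv: np.ndarray | None = None
    wavelengths_nm: np.ndarray | None = None
    trait: str = "y"

    @property
    def coef_(self) -> np.ndarray:
        """Regression vector (standardized space) at the selected n_LV."""
        return self.coef_by_lv[:, self.selected_n_lv - 1]

    def predict(self, X_new: np.ndarray, n_lv: int | None = None) -> np.ndarray:
        """Predict in original trait units: standardize, apply B, invert scaling."""
        a = self.selected_n_lv if n_lv is None else n_lv
        if not 1 <= a <= self.coef_by_lv.shape[1]:
            raise ValueError(f"n_lv={a} outside fitted range 1..{self.coef_by_lv.shape[1]}")
        Z = self.x_standardizer.apply(np.atleast_2d(np.asarray(X_new, dtype=float)))
        yhat_std = Z @ self.coef_by_lv[:, a - 1]
        return self.y_standardizer.invert(yhat_std).ravel()

    def summary(self) -> str:
        lines = [
            f"PLS calibration for {self.trait}",
            "=" * 40,
            f"latent variables considered : {self.coef_by_lv.shape[1]}",
            f"selected n_LV (min RMSE_CV) : {self.selected_n_lv}",
        ]
        if self.rmse_cv_by_lv is not None:
            lines.append(
                f"RMSE_CV at selection        : {self.rmse_cv_by_lv[self.selected_n_lv - 1]:.6g}"
            )
        lines.append(f"training samples            : {self.x_standardizer.fitted_on}")
        lines.append(f"predictor bands             : {self.weights.shape[0]}")
        return "\n".join(lines)


class PLSCalibration:
    """Partial least squares calibration of one trait on a spectra matrix.

    Parameters
    ----------
    X : (n, p) array
        Predictor matrix (preprocessed reflectance).
    y : (n,) array
        Trait values in original units.
    max_lv : int
        Largest latent-variable count to consider (default 25); clipped with a
        warning when it exceeds what the CV fold size or rank can support.
    cv : CVSpec
        Fold count and seed for RMSE_CV model selection.
    """

    def __init__(self, X, y, max_lv: int = 25, cv: CVSpec | None = None,
                 wavelengths_nm=None, trait: str = "y"):
        self.X = np.atleast_2d(np.asarray(X, dtype=float))
        self.y = np.asarray(y, dtype=float).ravel()
        if self.X.shape[0] != self.y.size:
            raise ValueError("X and y disagree on sample count")
        if np.std(self.y) == 0:
            raise ValueError("zero-variance response; nothing to calibrate")
        self.cv = cv or CVSpec()
        n, p = self.X.shape
        if n < self.cv.k:
            raise ValueError(f"n={n} below k={self.cv.k} folds")
        bound = min(n - math.ceil(n / self.cv.k) - 1, p)
        if max_lv > bound:
            warnings.warn(
                f"max_lv={max_lv} exceeds the rank bound {bound}; clipping",
                stacklevel=2,
            )
            max_lv = bound
        self.max_lv = max_lv
        self.wavelengths_nm = None if wavelengths_nm is None else np.asarray(wavelengths_nm)
        self.trait = trait

    @staticmethod
    def _fit_path(X_train, y_train, max_lv):
        """Standardize on the given data and return (xs, ys, W, P, q, T, B)."""
        xs = Standardizer.fit(X_train)
        ys = Standardizer.fit(y_train.reshape(-1, 1))
        Z = xs.apply(X_train)
        z_y = ys.apply(y_train.reshape(-1, 1)).ravel()
        W, P, q, T = _nipals(Z, z_y, max_lv)
        B = _coefficients_by_lv(W, P, q)
        return xs, ys, W, P, q, T, B

    def fit(self) -> PLSResults:
        def fit_predict(X_tr, y_tr, X_te):
            a_max = min(self.max_lv, X_tr.shape[0] - 1)
            xs, ys, _, _, _, _, B = self._fit_path(X_tr, y_tr, a_max)
            Z_te = xs.apply(X_te)
            preds_std = Z_te @ B  # (n_te, A_fit)
            preds = ys.invert(preds_std.reshape(-1, 1)).reshape(preds_std.shape)
            if preds.shape[1] < self.max_lv:
                # rank collapsed inside the fold: pad with the last usable model
                pad = np.repeat(preds[:, -1:], self.max_lv - preds.shape[1], axis=1)
                preds = np.hstack([preds, pad])
            return preds

        rmse_cv = cross_validate(fit_predict, self.X, self.y, self.cv)
        selected = int(np.argmin(rmse_cv)) + 1  # first minimum = fewest LVs

        xs, ys, W, P, q, T, B = self._fit_path(self.X, self.y, self.max_lv)
        selected = min(selected, B.shape[1])
        return PLSResults(
            x_standardizer=xs,
            y_standardizer=ys,
            weights=W,
            x_loadings=P,
            y_loadings=q,
            scores=T,
            coef_by_lv=B,
            selected_n_lv=selected,
            rmse_cv_by_lv=rmse_cv,
            wavelengths_nm=self.wavelengths_nm,
            trait=self.trait,
        )


# ---------------------------------------------------------------------------
# Linear epsilon-insensitive SVR (dual coordinate descent)
# ---------------------------------------------------------------------------

try:  # pragma: no cover - exercised implicitly by every SVR test
    from numba import njit
except ImportError:  # pragma: no cover
    njit = None


def _dcd_kernel(Q, y, C, epsilon, tol, max_passes, order_seed):
    """Coordinate sweeps on the SVR dual; see :func:`_dcd_svr`.

    Operates on the Gram matrix Q = X X'. The coordinate order is a fresh
    seeded permutation every pass (faster than cyclic sweeps on correlated
    spectra). Returns (beta, passes, converged).
    """
    n = Q.shape[0]
    beta = np.zeros(n)
    u = np.zeros(n)  # u = Q beta = training predictions X w
    np.random.seed(order_seed)
    converged = False
    passes = 0
    for passes in range(1, max_passes + 1):
        order = np.random.permutation(n)
        max_step = 0.0
        for idx in range(n):
            i = order[idx]
            a = Q[i, i]
            if a <= 0.0:
                continue
            b_lin = (u[i] - y[i]) - a * beta[i]
            if b_lin > epsilon:
                z = -(b_lin - epsilon) / a
            elif b_lin < -epsilon:
                z = -(b_lin + epsilon) / a
            else:
                z = 0.0
            if z > C:
                z = C
            elif z < -C:
                z = -C
            d = z - beta[i]
            if d != 0.0:
                beta[i] = z
                for j in range(n):
                    u[j] += d * Q[j, i]
                if abs(d) > max_step:
                    max_step = abs(d)
        # duality gap: primal 0.5 w'w + C sum max(0, |resid|-eps) vs
        # dual -(0.5 b'Qb - y'b + eps ||b||_1); both via u = Q beta
        wTw = 0.0
        hinge = 0.0
        yb = 0.0
        l1 = 0.0
        for j in range(n):
            wTw += beta[j] * u[j]
            r = abs(y[j] - u[j]) - epsilon
            if r > 0.0:
                hinge += r
            yb += y[j] * beta[j]
            l1 += abs(beta[j])
        primal = 0.5 * wTw + C * hinge
        dual = -(0.5 * wTw - yb + epsilon * l1)
        scale = primal if primal > 1e-12 else 1e-12
        if primal - dual <= tol * scale or max_step == 0.0:
            converged = True
            break
    return beta, passes, converged


if njit is not None:
    _dcd_kernel = njit(cache=False)(_dcd_kernel)


def _dcd_svr(X: np.ndarray, y: np.ndarray, C: float, epsilon: float,
             tol: float = 1e-6, max_passes: int = 10000,
             Q: np.ndarray | None = None):
    """Solve min_w 0.5 ||w||^2 + C sum_i max(0, |y_i - w.x_i| - eps) by
    coordinate descent on the dual.

    The dual is min_beta 0.5 b'Qb - y'b + eps ||b||_1 over the box
    [-C, C]^n with Q = X X', w = X' beta. No bias term: the data are assumed
    centered (standardized space), where the optimal intercept is zero.
    Converges when the relative duality gap drops below ``tol`` or after
    ``max_passes`` sweeps.

    Returns (w, beta, converged, n_passes).
    """
    if Q is None:
        Q = X @ X.T
    beta, passes, converged = _dcd_kernel(
        np.ascontiguousarray(Q, dtype=np.float64),
        np.ascontiguousarray(y, dtype=np.float64),
        float(C), float(epsilon), float(tol), int(max_passes), 0,
    )
    w = X.T @ beta
    return w, beta, converged, passes


def svr_dual_objective(X: np.ndarray, y: np.ndarray, beta: np.ndarray,
                       epsilon: float) -> float:
    """Dual objective 0.5 b'Qb - y'b + eps||b||_1 (to be minimized)."""
    u = X @ (X.T @ beta)
    return 0.5 * float(beta @ u) - float(y @ beta) + epsilon * float(np.sum(np.abs(beta)))


@dataclass
class SVRResults:
    """Fitted linear SVR calibration in standardized space."""

    x_standardizer: Standardizer
    y_standardizer: Standardizer
    coefficient_vector: np.ndarray
    intercept: float
    C: float
    epsilon: float
    rmse_cv_by_c: np.ndarray | None = None
    c_grid: tuple = DEFAULT_C_GRID
    converged: bool = True
    n_passes: int = 0
    trait: str = "y"

    def predict(self, X_new: np.ndarray) -> np.ndarray:
        Z = self.x_standardizer.apply(np.atleast_2d(np.asarray(X_new, dtype=float)))
        yhat_std = Z @ self.coefficient_vector + self.intercept
        return self.y_standardizer.invert(yhat_std).ravel()

    def summary(self) -> str:
        lines = [
            f"Linear SVR calibration for {self.trait}",
            "=" * 40,
            f"C grid searched   : {list(self.c_grid)}",
            f"selected C        : {self.C:g}",
            f"epsilon (std y)   : {self.epsilon:g}",
            f"converged         : {self.converged} ({self.n_passes} passes)",
            f"training samples  : {self.x_standardizer.fitted_on}",
        ]
        if self.rmse_cv_by_c is not None:
            best = self.rmse_cv_by_c[list(self.c_grid).index(self.C)]
            lines.append(f"RMSE_CV at selection: {best:.6g}")
        return "\n".join(lines)


class SVRCalibration:
    """Linear epsilon-insensitive SVR calibration with CV choice of C.

    epsilon defaults to 0.1 in standardized response units. The C grid is
    searched in ascending order and ties in RMSE_CV resolve to the smaller C.
    """

    def __init__(self, X, y, c_grid=DEFAULT_C_GRID, epsilon: float = 0.1,
                 cv: CVSpec | None = None, trait: str = "y",
                 tol: float = 1e-6, max_passes: int = 10000):
        self.X = np.atleast_2d(np.asarray(X, dtype=float))
        self.y = np.asarray(y, dtype=float).ravel()
        if self.X.shape[0] != self.y.size:
            raise ValueError("X and y disagree on sample count")
        c_grid = tuple(sorted(float(c) for c in c_grid))
        if any(c <= 0 for c in c_grid):
            raise ValueError("all C values must be positive")
        if epsilon <= 0:
            raise ValueError("epsilon must be positive")
        self.c_grid = c_grid
        self.epsilon = float(epsilon)
        self.cv = cv or CVSpec()
        self.trait = trait
        self.tol = tol
        self.max_passes = max_passes

    def _solve(self, X_tr, y_tr, C, Q=None):
        xs = Standardizer.fit(X_tr)
        if np.std(y_tr, ddof=1) == 0:
            # constant response: zero coefficients, predictions at the mean
            ys = Standardizer(np.array([y_tr.mean()]), np.array([1.0]), len(y_tr))
            return xs, ys, np.zeros(X_tr.shape[1]), True, 0
        ys = Standardizer.fit(y_tr.reshape(-1, 1))
        Z = xs.apply(X_tr)
        z_y = ys.apply(y_tr.reshape(-1, 1)).ravel()
        w, _, conv, passes = _dcd_svr(Z, z_y, C, self.epsilon,
                                      tol=self.tol, max_passes=self.max_passes,
                                      Q=Q)
        return xs, ys, w, conv, passes

    def fit(self) -> SVRResults:
        def fit_predict(X_tr, y_tr, X_te):
            # standardize once per fold; the Gram matrix is shared by all C
            xs = Standardizer.fit(X_tr)
            Z = xs.apply(X_tr)
            Q = Z @ Z.T
            cols = []
            for C in self.c_grid:
                xs_c, ys, w, _, _ = self._solve(X_tr, y_tr, C, Q=Q)
                Z_te = xs_c.apply(X_te)
                cols.append(ys.invert(Z_te @ w).ravel())
            return np.column_stack(cols)

        rmse_cv = cross_validate(fit_predict, self.X, self.y, self.cv)
        best_c = self.c_grid[int(np.argmin(rmse_cv))]  # ascending grid: ties -> smaller C

        xs, ys, w, conv, passes = self._solve(self.X, self.y, best_c)
        if not conv:
            warnings.warn(
                f"SVR solver hit {self.max_passes} passes without meeting the "
                f"duality-gap tolerance at C={best_c:g}", stacklevel=2,
            )
        return SVRResults(
            x_standardizer=xs,
            y_standardizer=ys,
            coefficient_vector=w,
            intercept=0.0,
            C=best_c,
            epsilon=self.epsilon,
            rmse_cv_by_c=rmse_cv,
            c_grid=self.c_grid,
            converged=conv,
            n_passes=passes,
            trait=self.trait,
        )


def fit_plsr(X, y, max_lv: int = 25, cv: CVSpec | None = None, **kw) -> PLSResults:
    """Functional wrapper: build a PLSCalibration and fit it."""
    return PLSCalibration(X, y, max_lv=max_lv, cv=cv, **kw).fit()


def fit_svr(X, y, c_grid=DEFAULT_C_GRID, epsilon: float = 0.1,
            cv: CVSpec | None = None, **kw) -> SVRResults:
    """Functional wrapper: build an SVRCalibration and fit it."""
    return SVRCalibration(X, y, c_grid=c_grid, epsilon=epsilon, cv=cv, **kw).fit()
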