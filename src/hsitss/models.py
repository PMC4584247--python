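"""Calibration models and evaluation statistics for TSS prediction.

Two model families are implemented:

* **PLSR** — partial least squares regression via NIPALS on mean-centered
  data (no variance scaling: reflectance bands share units). The fitted
  model collapses to a single regression vector plus intercept, which is
  what makes pixel-wise prediction of whole images cheap.

* **LS-SVM** — least-squares support vector regression. Training solves one
  (n+1) x (n+1) linear KKT system::

      [ 0    1^T          ] [ b     ]   [ 0 ]
      [ 1    K + I / gamma] [ alpha ] = [ y ]

  with kernel K either linear (x_k . x_l) or RBF exp(-||x_k - x_l||^2 /
  sigma2). Note the RBF convention: sigma2 is the full denominator, no
  factor 2 — the convention of the LS-SVM literature, where sigma2 is
  called the bandwidth. The stationarity condition of the Lagrangian forces
  sum(alpha) = 0, which every fit satisfies to numerical precision.

Model quality is reported as Pearson correlation R and RMSE on calibration,
leave-one-out cross-validation, and prediction sets (°Brix).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import linalg

from .errors import DegenerateResponseError, NumericallySingularError


# ---------------------------------------------------------------------------
# PLSR (NIPALS)
# ---------------------------------------------------------------------------

@dataclass
class PLSRModel:
    """Fitted PLS regression, reduced to coefficients + intercept."""

    n_lv: int
    coefficients: np.ndarray  # per trained band, on the original (uncentered) scale
    intercept: float
    x_mean: np.ndarray
    y_mean: float
    wavelengths: np.ndarray | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return X @ self.coefficients + self.intercept

    def to_dict(self) -> dict:
        return {
            "family": "plsr",
            "n_lv": int(self.n_lv),
            "coefficients": self.coefficients.tolist(),
            "intercept": float(self.intercept),
            "wavelengths": None
            if self.wavelengths is None
            else np.asarray(self.wavelengths).tolist(),
        }


def fit_plsr(
    X: np.ndarray,
    y: np.ndarray,
    n_lv: int,
    wavelengths: np.ndarray | None = None,
) -> PLSRModel:
    """NIPALS PLS1: X = T P' + E, y = U q' + f with inner relation U = B T.

    Components are extracted sequentially; each weight vector w maximizes
    covariance of the X-score t = X w with y, X is deflated by t p', and the
    model is collapsed to the standard regression vector
    B = W (P' W)^{-1} q acting on centered data.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if not 1 <= n_lv <= min(n - 1, p):
        raise ValueError(f"n_lv must lie in [1, {min(n - 1, p)}]")
    if np.ptp(y) == 0:
        raise DegenerateResponseError("response has zero variance")

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    yc = y - y_mean

    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    q = np.zeros(n_lv)
    Xd = Xc.copy()
    yd = yc.copy()
    k_used = n_lv
    for k in range(n_lv):
        w = Xd.T @ yd
        norm = np.linalg.norm(w)
        if norm < 1e-14 * max(1.0, np.abs(yd).max()):
            k_used = k  # residual X carries no further covariance with y
            break
        w /= norm
        t = Xd @ w
        tt = float(t @ t)
        if tt == 0.0:
            k_used = k
            break
        pk = Xd.T @ t / tt
        qk = float(yd @ t) / tt
        Xd -= np.outer(t, pk)
        yd = yd - qk * t
        W[:, k], P[:, k], q[k] = w, pk, qk
    W, P, q = W[:, :k_used], P[:, :k_used], q[:k_used]
    if k_used == 0:
        coef = np.zeros(p)
    else:
        coef = W @ linalg.solve_triangular(
            np.triu(P.T @ W), q, lower=False
        )  # P'W is upper triangular for NIPALS weights/loadings
    intercept = y_mean - float(x_mean @ coef)
    return PLSRModel(
        n_lv=n_lv,
        coefficients=coef,
        intercept=intercept,
        x_mean=x_mean,
        y_mean=y_mean,
        wavelengths=None if wavelengths is None else np.asarray(wavelengths, float),
    )


def select_n_lv(
    X: np.ndarray, y: np.ndarray, lv_max: int, cv: str = "loo"
) -> tuple[int, np.ndarray]:
    """Pick the LV count minimizing leave-one-out RMSECV over 1..lv_max.

    Returns (best LV count, rmse_cv per candidate). Smallest count wins ties.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    lv_max = int(min(lv_max, X.shape[0] - 2, X.shape[1]))
    rmses = np.empty(lv_max)
    for k in range(1, lv_max + 1):
        _, rmse, _ = loo_cv(X, y, lambda Xt, yt, k=k: fit_plsr(Xt, yt, k))
        rmses[k - 1] = rmse
    best = int(np.argmin(rmses)) + 1
    return best, rmses


# ---------------------------------------------------------------------------
# LS-SVM
# ---------------------------------------------------------------------------

def _kernel_matrix(
    A: np.ndarray, B: np.ndarray, kernel: str, sigma2: float | None
) -> np.ndarray:
    if kernel == "linear":
        return A @ B.T
    if kernel == "rbf":
        if sigma2 is None or sigma2 <= 0:
            raise ValueError("rbf kernel requires sigma2 > 0")
        d2 = (
            np.sum(A**2, axis=1)[:, None]
            + np.sum(B**2, axis=1)[None, :]
            - 2.0 * A @ B.T
        )
        return np.exp(-np.maximum(d2, 0.0) / sigma2)
    raise ValueError(f"unknown kernel {kernel!r}")


@dataclass
class LSSVMModel:
    """Dual-form least-squares SVM regressor: y(x) = sum_k alpha_k K(x, x_k) + b."""

    alpha: np.ndarray
    b: float
    kernel: str
    gamma: float
    sigma2: float | None
    support_X: np.ndarray
    wavelengths: np.ndarray | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        K = _kernel_matrix(X, self.support_X, self.kernel, self.sigma2)
        return K @ self.alpha + self.b

    def to_dict(self) -> dict:
        return {
            "family": "lssvm",
            "kernel": self.kernel,
            "gamma": float(self.gamma),
            "sigma2": None if self.sigma2 is None else float(self.sigma2),
            "alpha": self.alpha.tolist(),
            "b": float(self.b),
            "support_X": self.support_X.tolist(),
            "wavelengths": None
            if self.wavelengths is None
            else np.asarray(self.wavelengths).tolist(),
        }


def fit_lssvm(
    X: np.ndarray,
    y: np.ndarray,
    kernel: str = "rbf",
    gamma: float = 1.0,
    sigma2: float | None = None,
    wavelengths: np.ndarray | None = None,
) -> LSSVMModel:
    """Solve the LS-SVM KKT system for dual coefficients alpha and bias b."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if y.shape[0] != n:
        raise ValueError("X rows and y length differ")
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    K = _kernel_matrix(X, X, kernel, sigma2)
    A = np.zeros((n + 1, n + 1))
    A[0, 1:] = 1.0
    A[1:, 0] = 1.0
    A[1:, 1:] = K + np.eye(n) / gamma
    rhs = np.concatenate(([0.0], y))
    cond = np.linalg.cond(A)
    if not np.isfinite(cond) or cond > 1e14:
        raise NumericallySingularError("LS-SVM KKT system is singular", cond)
    sol = linalg.solve(A, rhs)
    return LSSVMModel(
        alpha=sol[1:],
        b=float(sol[0]),
        kernel=kernel,
        gamma=gamma,
        sigma2=sigma2,
        support_X=X,
        wavelengths=None if wavelengths is None else np.asarray(wavelengths, float),
    )


DEFAULT_GAMMA_GRID = np.logspace(0, 9, 13)
DEFAULT_SIGMA2_GRID = np.logspace(-2, 6, 17)


def grid_search_lssvm(
    X: np.ndarray,
    y: np.ndarray,
    kernel: str = "rbf",
    gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
    sigma2_grid: Sequence[float] = DEFAULT_SIGMA2_GRID,
) -> tuple[float, float | None, float]:
    """Exhaustive (gamma, sigma2) search minimizing leave-one-out RMSECV.

    For the linear kernel the sigma2 grid is ignored (the kernel has no
    bandwidth). Ties resolve to the smallest gamma, then smallest sigma2.
    """
    if len(gamma_grid) == 0:
        raise ValueError("gamma grid must be nonempty")
    if kernel == "linear":
        sigma2_candidates: list[float | None] = [None]
    else:
        if len(sigma2_grid) == 0:
            raise ValueError("sigma2 grid must be nonempty for the rbf kernel")
        sigma2_candidates = sorted(float(s) for s in sigma2_grid)
    best: tuple[float, float, float | None] | None = None  # (rmse, gamma, sigma2)
    for g in sorted(float(g) for g in gamma_grid):
        for s2 in sigma2_candidates:
            _, rmse, _ = loo_cv(
                X, y, lambda Xt, yt, g=g, s2=s2: fit_lssvm(Xt, yt, kernel, g, s2)
            )
            if best is None or rmse < best[0]:
                best = (rmse, g, s2)
    assert best is not None
    return best[1], best[2], best[0]


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def compute_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, float]:
    """(Pearson R, RMSE) between reference and predicted values."""
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.shape != y_pred.shape or y_true.size < 2:
        raise ValueError("need equal-length vectors with at least 2 entries")
    if np.ptp(y_true) == 0:
        raise DegenerateResponseError("R undefined for constant reference values")
    rmse = float(np.sqrt(np.mean((y_true - y_pred) ** 2)))
    if np.ptp(y_pred) == 0:
        r = 0.0  # constant predictions carry no correlation
    else:
        r = float(np.corrcoef(y_true, y_pred)[0, 1])
    return r, rmse


def loo_cv(
    X: np.ndarray,
    y: np.ndarray,
    model_factory: Callable[[np.ndarray, np.ndarray], object],
) -> tuple[float, float, np.ndarray]:
    """Leave-one-out CV: n fits on n-1 samples, each predicting the held-out one.

    Returns (r_cv, rmse_cv, held-out predictions). A failing inner fit is
    re-raised with the offending fold index attached.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if n < 3:
        raise ValueError("leave-one-out CV needs at least 3 samples")
    preds = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        try:
            model = model_factory(X[keep], y[keep])
            preds[i] = float(np.asarray(model.predict(X[i : i + 1])).ravel()[0])
        except Exception as exc:
            raise RuntimeError(f"leave-one-out fold {i} failed: {exc}") from exc
    r_cv, rmse_cv = compute_metrics(y, preds)
    return r_cv, rmse_cv, preds


def kfold_cv_rmse(
    X: np.ndarray,
    y: np.ndarray,
    model_factory: Callable[[np.ndarray, np.ndarray], object],
    n_folds: int = 5,
) -> float:
    """Contiguous k-fold cross-validated RMSE (cheap fitness for subset search)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if n < n_folds:
        raise ValueError("fewer samples than folds")
    bounds = np.linspace(0, n, n_folds + 1).astype(int)
    sq = 0.0
    for f in range(n_folds):
        test = np.zeros(n, dtype=bool)
        test[bounds[f] : bounds[f + 1]] = True
        model = model_factory(X[~test], y[~test])
        resid = y[test] - np.asarray(model.predict(X[test])).ravel()
        sq += float(resid @ resid)
    return float(np.sqrt(sq / n))


@dataclass
class MetricsReport:
    """Correlation/RMSE on the calibration, cross-validation and prediction sets."""

    r_c: float
    rmse_c: float
    r_cv: float
    rmse_cv: float
    r_p: float
    rmse_p: float
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            "R_C": self.r_c,
            "RMSE_C": self.rmse_c,
            "R_CV": self.r_cv,
            "RMSE_CV": self.rmse_cv,
            "R_P": self.r_p,
            "RMSE_P": self.rmse_p,
        }
        out.update(self.extras)
        return out


def round_sig(x: float, sig: int = 3) -> float:
    """Round to ``sig`` significant figures (0 stays 0)."""
    if x == 0:
        return 0.0
    from math import floor, log10

    return round(x, -int(floor(log10(abs(x)))) + (sig - 1))


def relative_change(reference: float, new: float) -> float:
    """Signed percent change 100 (new - reference) / reference, 3 sig. figures."""
    if reference == 0:
        raise ValueError("reference statistic must be nonzero")
    return round_sig(100.0 * (new - reference) / reference, 3)
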