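"""Random Frog wavelength selection.

Random Frog is a pseudo reversible-jump MCMC search over variable subsets.
Starting from a random subset of Q bands, each iteration proposes a subset
of a new size Q* ~ round(Normal(Q_current, theta * Q_current)), built by
adding candidate bands from the complement (over-sampling by a factor omega
and keeping the strongest regression coefficients) or by pruning the weakest
coefficients of the current subset. The candidate replaces the current
subset outright if its cross-validated sub-model error is no worse, and with
probability at most eta otherwise. A band's selection probability (SP) is
the fraction of iterations whose retained subset contains it; informative
bands accumulate high SP and are selected by an SP cut-off.

Defaults follow the chemometrics usage: T=10000 iterations, Q=50,
theta=0.3, omega=3, eta=0.1. A reduced T (a few hundred) already separates
informative from noise bands on synthetic data and is used in tests.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import SpectraTable
from .models import fit_plsr, kfold_cv_rmse


@dataclass
class FrogParams:
    """Search-control parameters; see module docstring for their roles."""

    T: int = 10000
    Q: int = 50
    theta: float = 0.3
    omega: float = 3.0
    eta: float = 0.1
    n_lv_max: int = 5
    cv_folds: int = 5
    seed: int = 0

    def validate(self, n_bands: int) -> None:
        if self.T < 1:
            raise ValueError("T must be >= 1")
        if not 1 <= self.Q <= n_bands:
            raise ValueError("Q must lie in [1, n_bands]")
        if self.theta <= 0:
            raise ValueError("theta must be positive")
        if self.omega < 1:
            raise ValueError("omega must be >= 1")
        if not 0 < self.eta <= 1:
            raise ValueError("eta must lie in (0, 1]")


@dataclass
class FrogResult:
    """Per-band selection probabilities and the accepted-subset size trace."""

    sp: np.ndarray
    inclusion_counts: np.ndarray
    trace: np.ndarray  # retained subset size per iteration
    T: int
    grid: np.ndarray = field(default=None)  # type: ignore[assignment]


def _sub_model_lv(n_vars: int, n_train: int, n_lv_max: int) -> int:
    return max(1, min(n_lv_max, n_vars, n_train - 1))


def _coef_ranked(X: np.ndarray, y: np.ndarray, subset: np.ndarray, keep: int,
                 n_lv_max: int) -> np.ndarray:
    """Keep the ``keep`` bands of ``subset`` with largest |PLS coefficient|."""
    n_lv = _sub_model_lv(subset.size, X.shape[0], n_lv_max)
    model = fit_plsr(X[:, subset], y, n_lv)
    order = np.argsort(-np.abs(model.coefficients), kind="stable")
    return np.sort(subset[order[:keep]])


def _fitness(X: np.ndarray, y: np.ndarray, subset: np.ndarray,
             params: FrogParams) -> float:
    n_train = X.shape[0] - X.shape[0] // params.cv_folds
    n_lv = _sub_model_lv(subset.size, n_train, params.n_lv_max)
    return kfold_cv_rmse(
        X[:, subset], y, lambda Xt, yt: fit_plsr(Xt, yt, min(n_lv, Xt.shape[0] - 1)),
        n_folds=params.cv_folds,
    )


def run_random_frog(table: SpectraTable, params: FrogParams) -> FrogResult:
    """Run the subset search and return per-band selection probabilities."""
    X, y = table.X, table.y
    n, p = X.shape
    params.validate(p)
    if n < params.cv_folds:
        raise ValueError("fewer samples than cross-validation folds")
    rng = np.random.default_rng(params.seed)

    current = np.sort(rng.choice(p, size=params.Q, replace=False))
    current_fitness = _fitness(X, y, current, params)

    counts = np.zeros(p, dtype=np.int64)
    trace = np.empty(params.T, dtype=np.int64)
    for it in range(params.T):
        q_cur = current.size
        q_star = int(np.clip(round(rng.normal(q_cur, params.theta * q_cur)), 1, p))

        if q_star > q_cur:
            n_new = min(int(params.omega * (q_star - q_cur)), p - q_cur)
            complement = np.setdiff1d(np.arange(p), current, assume_unique=False)
            extra = rng.choice(complement, size=n_new, replace=False)
            pool = np.concatenate([current, extra])
            candidate = _coef_ranked(X, y, pool, q_star, params.n_lv_max)
        elif q_star < q_cur:
            candidate = _coef_ranked(X, y, current, q_star, params.n_lv_max)
        else:
            candidate = current

        if candidate is current or np.array_equal(candidate, current):
            cand_fitness = current_fitness
            accept = True
        else:
            cand_fitness = _fitness(X, y, candidate, params)
            if cand_fitness <= current_fitness:
                accept = True
            else:
                p_accept = min(
                    params.eta, params.eta * current_fitness / cand_fitness
                )
                accept = rng.random() < p_accept
        if accept:
            current = candidate
            current_fitness = cand_fitness
        counts[current] += 1
        trace[it] = current.size

    return FrogResult(
        sp=counts / params.T,
        inclusion_counts=counts,
        trace=trace,
        T=params.T,
        grid=table.grid,
    )


def select_by_cutoff(
    result: FrogResult, grid: np.ndarray | None = None, cutoff: float = 0.7
) -> np.ndarray:
    """Wavelengths with SP >= cutoff, descending SP; ties by ascending wavelength."""
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError("cutoff must lie in [0, 1]")
    grid = np.asarray(result.grid if grid is None else grid, dtype=float)
    if grid.shape[0] != result.sp.shape[0]:
        raise ValueError("grid length does not match SP vector")
    keep = np.flatnonzero(result.sp >= cutoff)
    # sort by (-sp, wavelength): lexsort's last key is primary
    order = np.lexsort((grid[keep], -result.sp[keep]))
    return grid[keep[order]]
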