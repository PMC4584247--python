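"""PLSR / LS-SVM calibration models, cross-validation, grid search, metrics."""
import numpy as np
import pytest

from hsitss import (
    compute_metrics,
    fit_lssvm,
    fit_plsr,
    grid_search_lssvm,
    loo_cv,
    relative_change,
    select_n_lv,
)
from hsitss.errors import DegenerateResponseError


def _ols_predict(X, y, X_new):
    """Independent least-squares oracle via explicit normal equations."""
    A = np.column_stack([np.ones(X.shape[0]), X])
    beta = np.linalg.lstsq(A, y, rcond=None)[0]
    return np.column_stack([np.ones(X_new.shape[0]), X_new]) @ beta


class TestPLSR:
    def test_rank_one_single_component_fits_exactly(self):
        rng = np.random.default_rng(0)
        direction = rng.normal(size=6)
        scores = rng.normal(size=12)
        X = np.outer(scores, direction)
        y = 2.0 * scores + 1.0
        model = fit_plsr(X, y, 1)
        assert np.max(np.abs(model.predict(X) - y)) < 1e-10

    @pytest.mark.parametrize("n, p", [(8, 5), (10, 7), (9, 3)])
    def test_full_lv_matches_least_squares_oracle(self, n, p):
        rng = np.random.default_rng(n * p)
        X = rng.normal(size=(n, p))
        y = rng.normal(size=n)
        model = fit_plsr(X, y, p)
        expected = _ols_predict(X, y, X)
        assert np.max(np.abs(model.predict(X) - expected)) < 1e-8 * max(
            1.0, np.abs(expected).max()
        )

    def test_orthonormal_columns_coefficients_are_xty(self):
        rng = np.random.default_rng(4)
        raw = rng.normal(size=(12, 4))
        raw -= raw.mean(axis=0)           # zero-mean columns survive QR
        Q, _ = np.linalg.qr(raw)
        X = Q[:, :4]
        y = rng.normal(size=12)
        y -= y.mean()
        model = fit_plsr(X, y, 4)
        assert np.allclose(model.coefficients, X.T @ y, atol=1e-10)

    def test_adding_lv_never_raises_training_rmse(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(25, 10))
        y = X @ rng.normal(size=10) + 0.5 * rng.normal(size=25)
        rmses = []
        for k in range(1, 11):
            model = fit_plsr(X, y, k)
            _, rmse = compute_metrics(y, model.predict(X))
            rmses.append(rmse)
        assert np.all(np.diff(rmses) <= 1e-10)

    def test_matches_sklearn_nipals(self):
        """Cross-check against an independent NIPALS implementation."""
        from sklearn.cross_decomposition import PLSRegression

        rng = np.random.default_rng(11)
        X = rng.normal(size=(30, 12))
        y = X @ rng.normal(size=12) + rng.normal(size=30)
        for k in (1, 3, 6):
            ours = fit_plsr(X, y, k)
            ref = PLSRegression(n_components=k, scale=False).fit(X, y)
            assert np.allclose(
                ours.predict(X), ref.predict(X).ravel(), atol=1e-8
            )

    def test_invalid_lv_and_constant_y_rejected(self):
        X = np.random.default_rng(0).normal(size=(6, 4))
        with pytest.raises(ValueError):
            fit_plsr(X, np.arange(6.0), 0)
        with pytest.raises(ValueError):
            fit_plsr(X, np.arange(6.0), 6)
        with pytest.raises(DegenerateResponseError):
            fit_plsr(X, np.ones(6), 2)

    def test_select_n_lv_prefers_true_dimension(self):
        rng = np.random.default_rng(3)
        latent = rng.normal(size=(40, 2))
        X = latent @ rng.normal(size=(2, 15)) + 0.01 * rng.normal(size=(40, 15))
        y = latent @ np.array([1.5, -2.0])
        best, rmses = select_n_lv(X, y, 6)
        assert best == 2
        assert rmses[1] < rmses[0]


class TestLSSVM:
    def test_rbf_kernel_unit_diagonal(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(10, 5))
        model = fit_lssvm(X, rng.normal(size=10), "rbf", gamma=1.0, sigma2=2.0)
        from hsitss.models import _kernel_matrix

        K = _kernel_matrix(X, X, "rbf", 2.0)
        assert np.allclose(np.diag(K), 1.0)

    def test_ridge_limit_interpolates_linear_data(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(20, 4))
        y = X @ np.array([1.0, -2.0, 0.5, 3.0]) + 0.7
        model = fit_lssvm(X, y, "linear", gamma=1e8)
        assert np.max(np.abs(model.predict(X) - y)) < 1e-3 * np.ptp(y)

    def test_two_point_system_matches_hand_elimination(self):
        """n=2, x = {-1, +1}, y = {-1, +1}, linear kernel, gamma=1.

        KKT system   [0 1 1; 1 2 -1; 1 -1 2] [b, a1, a2] = [0, -1, 1],
        solved by hand-coded Gaussian elimination as the oracle.
        """
        A = np.array([[0.0, 1, 1], [1, 1 + 1, -1], [1, -1, 1 + 1]])
        rhs = np.array([0.0, -1.0, 1.0])
        M = np.column_stack([A, rhs]).astype(float)
        for col in range(3):  # partial-pivot elimination
            piv = col + np.argmax(np.abs(M[col:, col]))
            M[[col, piv]] = M[[piv, col]]
            M[col] /= M[col, col]
            for row in range(3):
                if row != col:
                    M[row] -= M[row, col] * M[col]
        b_ref, a1_ref, a2_ref = M[:, 3]
        model = fit_lssvm(np.array([[-1.0], [1.0]]), np.array([-1.0, 1.0]),
                          "linear", gamma=1.0)
        assert model.b == pytest.approx(b_ref, abs=1e-12)
        assert model.alpha == pytest.approx([a1_ref, a2_ref], abs=1e-12)

    @pytest.mark.parametrize("kernel, sigma2", [("linear", None), ("rbf", 3.0)])
    def test_dual_coefficients_sum_to_zero(self, kernel, sigma2):
        rng = np.random.default_rng(8)
        for _ in range(5):
            X = rng.normal(size=(15, 6))
            y = rng.normal(size=15)
            model = fit_lssvm(X, y, kernel, gamma=10.0, sigma2=sigma2)
            assert abs(model.alpha.sum()) < 1e-8 * max(1.0, np.linalg.norm(model.alpha))

    def test_matches_dense_bruteforce_solve(self):
        """Independent oracle: build the KKT matrix and solve with an
        elimination routine written here, for n <= 20."""
        rng = np.random.default_rng(5)
        for n in (5, 12, 20):
            X = rng.normal(size=(n, 4))
            y = rng.normal(size=n)
            gamma, sigma2 = 7.0, 1.5
            d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2)
            K = np.exp(-d2 / sigma2)
            A = np.zeros((n + 1, n + 1))
            A[0, 1:] = A[1:, 0] = 1.0
            A[1:, 1:] = K + np.eye(n) / gamma
            rhs = np.concatenate([[0.0], y])
            # hand-rolled Gauss-Jordan with partial pivoting
            M = np.column_stack([A, rhs])
            for col in range(n + 1):
                piv = col + np.argmax(np.abs(M[col:, col]))
                M[[col, piv]] = M[[piv, col]]
                M[col] /= M[col, col]
                for row in range(n + 1):
                    if row != col:
                        M[row] -= M[row, col] * M[col]
            sol = M[:, -1]
            model = fit_lssvm(X, y, "rbf", gamma=gamma, sigma2=sigma2)
            rel = max(1.0, np.abs(sol).max())
            assert abs(model.b - sol[0]) < 1e-8 * rel
            assert np.max(np.abs(model.alpha - sol[1:])) < 1e-8 * rel

    def test_invalid_gamma_and_missing_sigma2_rejected(self):
        X = np.zeros((3, 2))
        y = np.arange(3.0)
        with pytest.raises(ValueError):
            fit_lssvm(X, y, "linear", gamma=0.0)
        with pytest.raises(ValueError):
            fit_lssvm(np.random.default_rng(0).normal(size=(3, 2)), y, "rbf",
                      gamma=1.0, sigma2=None)


class TestLOOCV:
    def test_constant_predictor_closed_form(self):
        class Const:
            def predict(self, X):
                return np.full(X.shape[0], 5.0)

        y = np.array([4.0, 5.0, 7.0])
        X = np.zeros((3, 2))
        _, rmse, preds = loo_cv(X, y, lambda Xt, yt: Const())
        assert rmse == pytest.approx(np.sqrt(np.mean((y - 5.0) ** 2)))
        assert np.allclose(preds, 5.0)

    def test_mean_predictor_leaves_one_out(self):
        class Mean:
            def __init__(self, y):
                self.c = y.mean()

            def predict(self, X):
                return np.full(X.shape[0], self.c)

        y = np.array([1.0, 2.0, 6.0])
        X = np.zeros((3, 1))
        _, _, preds = loo_cv(X, y, lambda Xt, yt: Mean(yt))
        expected = [(2 + 6) / 2, (1 + 6) / 2, (1 + 2) / 2]
        assert np.allclose(preds, expected)

    def test_plsr_recipe_beats_mean_predictor_on_linear_data(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(20, 5))
        y = X @ rng.normal(size=5)
        _, rmse_pls, _ = loo_cv(X, y, lambda Xt, yt: fit_plsr(Xt, yt, 5))
        rmse_mean = np.sqrt(np.mean((y - y.mean()) ** 2))
        assert rmse_pls < rmse_mean

    def test_fold_failure_reports_index(self):
        def bad_factory(Xt, yt):
            raise RuntimeError("boom")

        with pytest.raises(RuntimeError, match="fold 0"):
            loo_cv(np.zeros((3, 1)), np.arange(3.0), bad_factory)


class TestGridSearch:
    def test_single_point_grid_returned(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(10, 3))
        y = rng.normal(size=10)
        g, s2, _ = grid_search_lssvm(X, y, "rbf", [4.0], [2.0])
        assert (g, s2) == (4.0, 2.0)

    def test_evaluation_count_matches_grid_cardinality(self, monkeypatch):
        calls = []
        import hsitss.models as mod

        original = mod.loo_cv

        def counting(X, y, factory):
            calls.append(1)
            return original(X, y, factory)

        monkeypatch.setattr(mod, "loo_cv", counting)
        rng = np.random.default_rng(1)
        X = rng.normal(size=(8, 3))
        y = rng.normal(size=8)
        mod.grid_search_lssvm(X, y, "rbf", [1.0], [0.5, 5.0])
        assert len(calls) == 2

    def test_linear_kernel_ignores_sigma2_grid(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(10, 3))
        y = X @ np.array([1.0, 2.0, -1.0])
        g, s2, _ = grid_search_lssvm(X, y, "linear", [1.0, 100.0], [0.1, 1.0, 10.0])
        assert s2 is None

    def test_recovers_planted_rbf_bandwidth_within_one_step(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(-2, 2, size=(40, 2))
        centers = X[:5]
        true_sigma2 = 1.0
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        y = np.exp(-d2 / true_sigma2) @ np.array([2.0, -1.5, 1.0, 0.5, -2.0])
        grid = [0.01, 0.1, 1.0, 10.0, 100.0]
        _, s2, _ = grid_search_lssvm(X, y, "rbf", [100.0], grid)
        assert s2 in (0.1, 1.0, 10.0)  # within one grid step of the truth


class TestMetrics:
    def test_perfect_prediction(self):
        y = np.array([1.0, 2.0, 3.0])
        r, rmse = compute_metrics(y, y)
        assert (r, rmse) == (pytest.approx(1.0), pytest.approx(0.0))

    def test_pure_offset_keeps_unit_correlation(self):
        y = np.array([1.0, 2.0, 3.0])
        r, rmse = compute_metrics(y, y + 1.0)
        assert r == pytest.approx(1.0)
        assert rmse == pytest.approx(1.0)

    def test_constant_prediction_rmse(self):
        r, rmse = compute_metrics(np.array([1.0, 2.0, 3.0]), np.array([2.0, 2.0, 2.0]))
        assert rmse == pytest.approx(np.sqrt(2.0 / 3.0))

    def test_constant_reference_rejected(self):
        with pytest.raises(DegenerateResponseError):
            compute_metrics(np.ones(4), np.arange(4.0))


class TestRelativeChange:
    @pytest.mark.parametrize(
        "ref, new, expected",
        [
            (0.956, 0.925, -3.24),
            (0.430, 0.557, 29.5),
            (460.0, 23.0, -95.0),
        ],
    )
    def test_model_comparison_arithmetic(self, ref, new, expected):
        assert relative_change(ref, new) == pytest.approx(expected, abs=0.005)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            relative_change(0.0, 1.0)

    def test_sign_preserved(self):
        assert relative_change(2.0, 3.0) == 50.0
        assert relative_change(2.0, 1.0) == -50.0
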