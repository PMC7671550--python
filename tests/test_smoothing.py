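"""Penalized B-spline fitting, GCV selection, and the TGCV grid search."""

import numpy as np
import pytest

from fclustfd.smoothing import (
    BasisSpec,
    PenalizedBSplineSmoother,
    build_basis,
    evaluate_curve,
    fit_penalized,
    penalty_matrix,
    select_lambda,
    tgcv_grid_search,
)


class TestBasis:
    @pytest.mark.parametrize("q, m, s", [(15, 4, 19), (0, 4, 4), (5, 6, 11)])
    def test_dimension_is_knots_plus_order(self, q, m, s):
        spec = BasisSpec((0.0, 1.0), q, m)
        assert spec.size == s
        Phi = build_basis(spec).design_matrix(np.linspace(0, 1, 17))
        assert Phi.shape == (17, s)

    def test_partition_of_unity(self, rng):
        spec = BasisSpec((1.0, 40.0), 15, 4)
        t = rng.uniform(1.0, 40.0, size=200)
        Phi = build_basis(spec).design_matrix(t)
        np.testing.assert_allclose(Phi.sum(axis=1), 1.0, atol=1e-12)
        assert (Phi >= -1e-14).all()

    def test_out_of_domain_rejected(self):
        basis = build_basis(BasisSpec((0.0, 1.0), 3, 4))
        with pytest.raises(ValueError):
            basis.design_matrix([1.5])

    @pytest.mark.parametrize("bad", [
        dict(domain=(1.0, 1.0), n_knots=3),
        dict(domain=(0.0, 1.0), n_knots=-1),
        dict(domain=(0.0, 1.0), n_knots=3, order=0),
        dict(domain=(0.0, 1.0), n_knots=3, order=2, penalty_order=2),
    ])
    def test_invalid_specs_rejected(self, bad):
        with pytest.raises(ValueError):
            BasisSpec(**bad)


def simpson_weights(t: np.ndarray) -> np.ndarray:
    """Composite-Simpson weights on an odd-length equally spaced grid."""
    h = t[1] - t[0]
    w = np.ones(len(t))
    w[1:-1:2] = 4.0
    w[2:-1:2] = 2.0
    return w * h / 3.0


class TestPenaltyMatrix:
    @pytest.mark.parametrize("q, m", [(5, 4), (10, 4), (5, 6)])
    def test_matches_dense_simpson_quadrature(self, q, m):
        spec = BasisSpec((0.0, 1.0), q, m)
        R = penalty_matrix(spec)
        basis = build_basis(spec)
        breaks = np.concatenate([[0.0], spec.interior_knots(), [1.0]])
        oracle = np.zeros_like(R)
        for a, b in zip(breaks[:-1], breaks[1:]):
            t = np.linspace(a, b, 257)
            D2 = basis.derivative_matrix(t, 2)
            oracle += np.einsum("ta,tb->ab", D2 * simpson_weights(t)[:, None], D2)
        np.testing.assert_allclose(R, oracle, atol=1e-8)

    def test_symmetric_positive_semidefinite(self):
        R = penalty_matrix(BasisSpec((1.0, 40.0), 15, 4))
        np.testing.assert_array_equal(R, R.T)
        assert np.linalg.eigvalsh(R).min() > -1e-10

    def test_straight_line_in_nullspace(self):
        spec = BasisSpec((0.0, 1.0), 15, 4)
        t = np.linspace(0, 1, 50)
        Phi = build_basis(spec).design_matrix(t)
        c, *_ = np.linalg.lstsq(Phi, 0.7 - 1.3 * t, rcond=None)
        assert c @ penalty_matrix(spec) @ c < 1e-10


class TestFitPenalized:
    def test_zero_lambda_equals_unpenalized_least_squares(self, noisy_sine):
        t, y, _ = noisy_sine
        spec = BasisSpec((0.0, 1.0), 10, 4)
        fit = fit_penalized(y, t, spec, 0.0)
        Phi = build_basis(spec).design_matrix(t)
        c_ls, *_ = np.linalg.lstsq(Phi, y, rcond=None)
        np.testing.assert_allclose(fit.coefficients, c_ls, atol=1e-8)
        assert fit.df == pytest.approx(spec.size)
        assert fit.gcv == pytest.approx(len(y) * fit.sse / (len(y) - spec.size) ** 2)

    def test_saturated_basis_interpolates(self, noisy_sine):
        t, y, _ = noisy_sine
        spec = BasisSpec((0.0, 1.0), len(y) - 4, 4)  # s = v
        fit = fit_penalized(y, t, spec, 0.0)
        assert fit.sse / (y @ y) < 1e-12
        assert np.isinf(fit.gcv)  # df = v saturates the GCV denominator

    def test_huge_lambda_recovers_ols_line(self, noisy_sine):
        t, y, _ = noisy_sine
        fit = fit_penalized(y, t, BasisSpec((0.0, 1.0), 15, 4), 1e20)
        X = np.column_stack([np.ones_like(t), t])
        line = X @ np.linalg.lstsq(X, y, rcond=None)[0]
        np.testing.assert_allclose(
            evaluate_curve(fit, BasisSpec((0.0, 1.0), 15, 4), t), line, atol=1e-4
        )
        assert fit.df == pytest.approx(2.0, abs=0.01)

    def test_sse_nondecreasing_df_nonincreasing_in_lambda(self, noisy_sine):
        t, y, _ = noisy_sine
        spec = BasisSpec((0.0, 1.0), 12, 4)
        fits = [fit_penalized(y, t, spec, lam) for lam in 10.0 ** np.arange(-10.0, 11.0)]
        sse = [f.sse for f in fits]
        df = [f.df for f in fits]
        assert all(a <= b + 1e-10 for a, b in zip(sse, sse[1:]))
        assert all(a >= b - 1e-10 for a, b in zip(df, df[1:]))

    def test_time_axis_rescaling_invariance_unpenalized(self, noisy_sine):
        t, y, _ = noisy_sine
        fit_a = fit_penalized(y, t, BasisSpec((0.0, 1.0), 8, 4), 0.0)
        t_b = 5.0 + 30.0 * t
        fit_b = fit_penalized(y, t_b, BasisSpec((5.0, 35.0), 8, 4), 0.0)
        np.testing.assert_allclose(fit_a.coefficients, fit_b.coefficients, atol=1e-8)

    def test_invalid_inputs(self, noisy_sine):
        t, y, _ = noisy_sine
        spec = BasisSpec((0.0, 1.0), 5, 4)
        with pytest.raises(ValueError):
            fit_penalized(y, t, spec, -1.0)
        with pytest.raises(ValueError):
            fit_penalized(y[:1], t[:1], spec, 0.0)


class TestSelectLambda:
    def test_matches_independent_exhaustive_search(self, noisy_sine):
        t, y, _ = noisy_sine
        spec = BasisSpec((0.0, 1.0), 10, 4)
        grid = np.arange(-8.0, 8.0, 0.5)
        lam, gcv = select_lambda(y, t, spec, grid)
        # independent re-evaluation through the single-fit path
        direct = [(10.0**g, fit_penalized(y, t, spec, 10.0**g).gcv) for g in grid]
        best = min(direct, key=lambda pair: pair[1])
        assert lam == pytest.approx(best[0])
        assert gcv == pytest.approx(best[1], rel=1e-10)

    def test_single_point_grid(self, noisy_sine):
        t, y, _ = noisy_sine
        lam, _ = select_lambda(y, t, BasisSpec((0.0, 1.0), 10, 4), [0.3])
        assert lam == pytest.approx(10.0**0.3)


class TestEvaluateCurve:
    def test_constant_coefficients_give_constant_curve(self, rng):
        spec = BasisSpec((0.0, 1.0), 7, 4)
        t = rng.uniform(0, 1, size=30)
        np.testing.assert_allclose(
            evaluate_curve(np.full(spec.size, 2.5), spec, t), 2.5, atol=1e-12
        )

    def test_greville_coefficients_reproduce_identity(self):
        # linear-in-t coefficient vector (Greville abscissae) -> x(t) = t
        spec = BasisSpec((0.0, 1.0), 9, 4)
        knots = spec.knot_vector()
        greville = np.array(
            [knots[p + 1 : p + spec.order].mean() for p in range(spec.size)]
        )
        t = np.linspace(0, 1, 41)
        np.testing.assert_allclose(evaluate_curve(greville, spec, t), t, atol=1e-12)

    def test_consistent_with_fitted_values(self, noisy_sine):
        t, y, _ = noisy_sine
        spec = BasisSpec((0.0, 1.0), 10, 4)
        fit = fit_penalized(y, t, spec, 1.0)
        np.testing.assert_allclose(evaluate_curve(fit, spec, t), y - fit.residuals)


class TestTgcvGridSearch:
    def make_cohort(self, n=6, v=40, seed=0):
        rng = np.random.default_rng(seed)
        t = np.arange(1.0, v + 1)
        base = np.sin(2 * np.pi * (t - 1) / (v - 1))
        X = base + 0.1 * rng.standard_normal((n, v))
        return X, t

    def test_single_unit_single_config_reduces_to_gcv(self):
        X, t = self.make_cohort(n=1)
        grid = np.arange(-6.0, 6.0, 0.5)
        result = tgcv_grid_search(X, t, q_options=(8,), m_options=(4,), grid=grid)
        lam, gcv = select_lambda(X[0], t, BasisSpec((1.0, 40.0), 8, 4), grid)
        assert result.lambda_ == pytest.approx(lam)
        assert result.tgcv == pytest.approx(gcv)

    def test_selected_row_minimizes_tgcv(self):
        X, t = self.make_cohort()
        result = tgcv_grid_search(
            X, t, q_options=(5, 10), m_options=(4, 6), grid=np.arange(-6.0, 6.0, 0.5)
        )
        assert result.tgcv == pytest.approx(result.table["TGCV"].min())
        assert not result.override_applied
        # per-unit breakdown sums to the tabulated TGCV
        for (q, m), gcvs in result.per_unit_gcv.items():
            row = result.table[(result.table["q"] == q) & (result.table["m"] == m)]
            assert gcvs.sum() == pytest.approx(float(row["TGCV"].iloc[0]))

    def test_parsimony_override_prefers_simpler_model(self):
        X, t = self.make_cohort()
        strict = tgcv_grid_search(
            X, t, q_options=(5, 10, 15), m_options=(4,), grid=np.arange(-6.0, 6.0, 0.5)
        )
        lenient = tgcv_grid_search(
            X, t, q_options=(5, 10, 15), m_options=(4,),
            grid=np.arange(-6.0, 6.0, 0.5), parsimony_tol=1e9,
        )
        assert lenient.selected == (5, 4)  # simplest model within a huge tolerance
        assert lenient.override_applied == (strict.selected != (5, 4))

    def test_missing_values_rejected(self):
        X, t = self.make_cohort()
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            tgcv_grid_search(X, t)


class TestSmootherEstimator:
    def test_fit_transform_roundtrip(self):
        rng = np.random.default_rng(3)
        t = np.arange(1.0, 41.0)
        X = np.sin(2 * np.pi * (t - 1) / 39) + 0.05 * rng.standard_normal((8, 40))
        sm = PenalizedBSplineSmoother(n_knots=10, order=4).fit(X)
        assert sm.coef_.shape == (8, 14)
        # transform reproduces the fitted coefficients
        np.testing.assert_allclose(sm.transform(X), sm.coef_, atol=1e-8)
        curves = sm.inverse_transform(sm.coef_)
        assert curves.shape == X.shape
        # smoother output is closer to the signal than the raw data
        signal = np.sin(2 * np.pi * (t - 1) / 39)
        assert np.mean((curves - signal) ** 2) < np.mean((X - signal) ** 2)

    def test_fixed_lambda_honored(self):
        t = np.arange(1.0, 31.0)
        X = np.outer(np.ones(3), np.log(t))
        sm = PenalizedBSplineSmoother(n_knots=5, smoothing=0.5).fit(X)
        assert sm.lambda_ == 0.5

    def test_sklearn_param_interface(self):
        sm = PenalizedBSplineSmoother()
        assert sm.get_params()["n_knots"] == 15
        sm.set_params(n_knots=5, order=6)
        assert sm.n_knots == 5 and sm.order == 6
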