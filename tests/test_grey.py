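"""Grey models: AGO, GM(1,1), multivariate MGM, coupled system, ODE solution."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from greycast import GM11, MGM, MGMSystem, affine_ode_solution, ago, fit_mgm
from greycast.grey import DegenerateModelError, EstimationWarning, inverse_ago, round_counts
from greycast.synthetic import gen_gm11_series, gen_linear_system_panel, random_stable_system


class TestAGO:
    def test_cumulative_and_background(self):
        acc = ago([489, 1510, 1501])
        np.testing.assert_array_equal(acc.ago, [489, 1999, 3500])
        np.testing.assert_array_equal(acc.background, [1244, 2749.5])

    def test_unit_sequence(self):
        acc = ago([1, 1, 1, 1])
        np.testing.assert_array_equal(acc.ago, [1, 2, 3, 4])
        np.testing.assert_array_equal(acc.background, [1.5, 2.5, 3.5])

    def test_single_element_has_no_background(self):
        acc = ago([5])
        np.testing.assert_array_equal(acc.ago, [5])
        assert acc.background.size == 0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ago([])

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.integers(0, 10**9), min_size=1, max_size=30))
    def test_difference_roundtrip_exact_for_integers(self, values):
        acc = ago(values)
        np.testing.assert_array_equal(inverse_ago(acc.ago), np.asarray(values, float))


class TestAffineODESolution:
    def test_zero_matrix_limit(self):
        A = np.zeros((2, 2))
        v = np.array([1.0, 2.0])
        B = np.array([3.0, 4.0])
        np.testing.assert_allclose(affine_ode_solution(A, 2.5, v, B), v + 2.5 * B)

    def test_scalar_closed_form(self):
        out = affine_ode_solution([[-1.0]], 1.0, [1.0], [0.0])
        np.testing.assert_allclose(out, [np.exp(-1.0)], rtol=1e-12)

    def test_matches_explicit_inverse_formula(self):
        rng = np.random.default_rng(7)
        A = rng.normal(size=(3, 3)) * 0.4
        v = rng.normal(size=3)
        B = rng.normal(size=3)
        t = 1.7
        expected = expm(A * t) @ v + np.linalg.inv(A) @ (expm(A * t) - np.eye(3)) @ B
        np.testing.assert_allclose(
            affine_ode_solution(A, t, v, B), expected, atol=1e-10
        )

    def test_matches_numerical_integration(self):
        rng = np.random.default_rng(11)
        A = rng.normal(size=(3, 3)) * 0.3
        v = rng.uniform(1, 5, 3)
        B = rng.uniform(1, 5, 3)
        sol = solve_ivp(
            lambda _, x: A @ x + B, (0.0, 2.0), v, rtol=1e-12, atol=1e-12
        )
        np.testing.assert_allclose(
            affine_ode_solution(A, 2.0, v, B), sol.y[:, -1], atol=1e-8
        )

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            affine_ode_solution(np.eye(2), 1.0, [1.0], [1.0, 2.0])


class TestGM11:
    def test_michigan_totals_fit_quality(self, michigan):
        res = GM11(michigan.dependent_array).fit()
        actual = michigan.dependent_array
        fitted = res.fitted_counts
        mape = np.mean(np.abs((actual - fitted) / actual)) * 100
        assert mape == pytest.approx(8.30, abs=0.01)

    def test_first_fitted_value_is_anchored(self, michigan):
        res = GM11(michigan.dependent_array).fit()
        assert res.fittedvalues[0] == michigan.dependent[0]

    def test_parameter_recovery_noise_free(self):
        series, truth = gen_gm11_series(a=-0.1, b=100.0, x1=50.0, n=8)
        res = GM11(series).fit()
        # adjacent-mean background induces O(a^2) bias, well inside 5%
        assert res.a == pytest.approx(truth["a"], rel=0.05)
        assert res.b == pytest.approx(truth["b"], rel=0.05)

    def test_constant_series_is_degenerate(self):
        with pytest.raises(DegenerateModelError):
            GM11([7.0, 7.0, 7.0, 7.0, 7.0]).fit()

    def test_nonpositive_series_rejected(self):
        with pytest.raises(ValueError):
            GM11([1.0, -2.0, 3.0, 4.0])

    def test_forecast_continues_the_response(self):
        series, _ = gen_gm11_series(a=-0.1, b=100.0, x1=50.0, n=10)
        res = GM11(series[:8]).fit()
        fc = res.forecast(2)
        # adjacent-mean background induces O(a^2) estimation bias, so the
        # continuation is tracked at the ~1% level, not to machine precision
        np.testing.assert_allclose(fc, series[8:10], rtol=1e-2)

    def test_bad_horizon(self):
        res = GM11([10.0, 12.0, 15.0, 19.0]).fit()
        with pytest.raises(ValueError):
            res.forecast(0)


class TestMGM:
    def test_michigan_fitted_counts_match_reference_table(self, michigan):
        res = fit_mgm(michigan, ("X1", "X2", "X3", "X6"))
        np.testing.assert_array_equal(
            res.fitted_counts, [489, 1308, 1653, 1910, 1308, 1734]
        )

    def test_factor_order_does_not_change_the_fit(self, michigan):
        a = fit_mgm(michigan, ("X1", "X2", "X3", "X6")).fittedvalues
        b = fit_mgm(michigan, ("X6", "X3", "X1", "X2")).fittedvalues
        np.testing.assert_allclose(a, b, rtol=1e-9)

    def test_initial_condition_anchor(self, michigan):
        res = fit_mgm(michigan, ("X1", "X2", "X3", "X6"))
        assert res.fittedvalues[0] == michigan.dependent[0]

    def test_least_squares_residual_orthogonal_to_design(self, michigan):
        res = fit_mgm(michigan, ("X3", "X6"))
        acc = ago(michigan.dependent_array)
        factor_ago = np.cumsum(
            np.vstack([michigan.factor_array(f) for f in ("X3", "X6")]), axis=1
        )
        P = np.column_stack([-acc.background, factor_ago[:, 1:].T])
        coef = np.concatenate([[res.a], res.b])
        resid = michigan.dependent_array[1:] - P @ coef
        np.testing.assert_allclose(P.T @ resid, 0.0, atol=1e-6)

    def test_rank_deficient_design_warns_and_uses_min_norm(self, michigan):
        with pytest.warns(EstimationWarning):
            res = fit_mgm(michigan, ("X1", "X2", "X3", "X5", "X6"))
        assert np.all(np.isfinite(res.fittedvalues))

    def test_forecast_requires_positive_horizon(self, michigan):
        res = fit_mgm(michigan, ("X1", "X2", "X3", "X6"))
        with pytest.raises(ValueError):
            res.forecast(0)

    def test_forecast_extends_the_series(self, michigan):
        res = fit_mgm(michigan, ("X1", "X2", "X3", "X6"))
        fc = res.forecast(2)
        assert fc.shape == (2,)
        assert np.all(np.isfinite(fc))


class TestMGMSystem:
    def test_single_variable_equivalence_with_gm11(self, michigan):
        dep = michigan.dependent_array
        gm = GM11(dep).fit()
        sys_res = MGMSystem(dep[None, :]).fit()
        assert -sys_res.A[0, 0] == pytest.approx(gm.a, abs=1e-9)
        assert sys_res.B[0] == pytest.approx(gm.b, abs=1e-9)
        np.testing.assert_allclose(
            sys_res.fittedvalues[0], gm.fittedvalues, atol=1e-9
        )

    def test_parameter_recovery_noise_free(self):
        spec = random_stable_system(m=3, seed=5, n=10)
        panel, truth = gen_linear_system_panel(spec)
        rows = [panel.dependent_array] + [
            panel.factor_array(f) for f in panel.factor_ids
        ]
        res = MGMSystem(np.vstack(rows)).fit()
        np.testing.assert_allclose(res.A, truth["A"], rtol=0.05, atol=1e-3)
        np.testing.assert_allclose(res.B, truth["B"], rtol=0.05)

    def test_noise_free_forecast_matches_ode_continuation(self):
        spec = random_stable_system(m=2, seed=3, n=12)
        panel, truth = gen_linear_system_panel(spec)
        full_X1 = np.column_stack(
            [
                affine_ode_solution(truth["A"], t - 1.0, truth["x0"], truth["B"])
                for t in range(1, 15)
            ]
        )
        continuation = np.diff(full_X1, axis=1)[:, 11:]
        rows = [panel.dependent_array] + [
            panel.factor_array(f) for f in panel.factor_ids
        ]
        fc = MGMSystem(np.vstack(rows)).fit().forecast(2)
        # trapezoidal background values bias the estimate by O(rho^2), so
        # the true continuation is tracked at the sub-percent level
        np.testing.assert_allclose(fc, continuation, rtol=1e-2)

    def test_initial_condition_anchor_all_variables(self):
        spec = random_stable_system(m=3, seed=9, n=8)
        panel, _ = gen_linear_system_panel(spec)
        rows = np.vstack(
            [panel.dependent_array]
            + [panel.factor_array(f) for f in panel.factor_ids]
        )
        res = MGMSystem(rows).fit()
        np.testing.assert_allclose(res.fittedvalues[:, 0], rows[:, 0], rtol=1e-12)


class TestRounding:
    @pytest.mark.parametrize(
        "value, expected",
        [(0.5, 1.0), (1.5, 2.0), (2.5, 3.0), (-0.5, -1.0), (-1.5, -2.0), (1.49, 1.0)],
    )
    def test_half_away_from_zero(self, value, expected):
        assert round_counts([value])[0] == expected
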