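"""Residual states, transition estimation and Markov correction."""

import itertools
from fractions import Fraction

import numpy as np
import pytest

from greycast import MarkovCorrection, fit_mgm
from greycast.markov import (
    StatePartition,
    ZeroWidthError,
    assign_states,
    correct_fitted,
    estimate_transitions,
    forecast_corrected,
    future_state_distribution,
    kstep,
    partition_states,
    residuals,
)

F = Fraction

# the Michigan chain: states of the six MGM(1,4) residuals, 0-based
MICHIGAN_STATES = [1, 2, 0, 0, 1, 1]


@pytest.fixture(scope="module")
def michigan_chain(michigan):
    fitted = fit_mgm(michigan, ("X1", "X2", "X3", "X6")).fitted_counts
    return MarkovCorrection.from_series(michigan.dependent_array, fitted)


class TestResiduals:
    @pytest.mark.parametrize(
        "actual, fitted, expected",
        [(1510.0, 1308.0, 0.1338), (1501.0, 1653.0, -0.1013)],
    )
    def test_actual_denominator_matches_reference_table(self, actual, fitted, expected):
        delta = residuals([actual], [fitted], "actual")
        assert round(float(delta[0]), 4) == expected

    def test_exact_fit_gives_zero_under_both_conventions(self):
        for den in ("actual", "fitted"):
            assert residuals([100.0], [100.0], den)[0] == 0.0

    def test_fitted_denominator_is_the_literal_grey_form(self):
        delta = residuals([110.0], [100.0], "fitted")
        assert delta[0] == pytest.approx(0.1)

    def test_zero_denominator_raises(self):
        with pytest.raises(ZeroDivisionError):
            residuals([1.0], [0.0], "fitted")


class TestPartition:
    def test_michigan_three_state_bounds(self, michigan_chain):
        edges = michigan_chain.partition.edges
        np.testing.assert_array_equal(
            np.round(edges, 4), [-0.1013, -0.0229, 0.0554, 0.1338]
        )

    def test_equal_thirds(self):
        part = partition_states([0.0, 0.1, 0.25, 0.3], 3)
        np.testing.assert_allclose(part.edges, [0.0, 0.1, 0.2, 0.3])

    def test_two_states(self):
        part = partition_states([-1.0, 0.5, 1.0], 2)
        np.testing.assert_allclose(part.edges, [-1.0, 0.0, 1.0])

    def test_identical_residuals_rejected(self):
        with pytest.raises(ZeroWidthError):
            partition_states([0.05, 0.05, 0.05], 3)


class TestAssignment:
    def test_michigan_state_sequence(self, michigan_chain):
        np.testing.assert_array_equal(michigan_chain.states, MICHIGAN_STATES)

    def test_maximum_residual_joins_the_last_closed_interval(self):
        part = partition_states([0.0, 0.3], 3)
        assert assign_states([0.3], part)[0] == 2

    def test_interior_boundary_belongs_to_the_upper_state(self):
        part = StatePartition(edges=np.array([-0.1013, -0.0229, 0.0554, 0.1338]))
        assert assign_states([-0.0229], part)[0] == 1

    def test_out_of_range_rejected(self):
        part = partition_states([0.0, 0.3], 3)
        with pytest.raises(ValueError):
            assign_states([0.4], part)


class TestTransitions:
    def test_michigan_one_step_matrix_exact(self, michigan_chain):
        assert michigan_chain.transitions.P_frac == (
            (F(1, 2), F(1, 2), F(0)),
            (F(0), F(1, 2), F(1, 2)),
            (F(1), F(0), F(0)),
        )
        np.testing.assert_array_equal(
            michigan_chain.transitions.row_counts, [2, 2, 1]
        )

    def test_rows_sum_to_one(self, michigan_chain):
        np.testing.assert_allclose(michigan_chain.transitions.P.sum(axis=1), 1.0)

    def test_single_state_chain_pads_unvisited_rows(self):
        with pytest.warns(UserWarning, match="uniform"):
            trans = estimate_transitions([0, 0, 0], s=3)
        assert trans.P_frac[0] == (F(1), F(0), F(0))
        assert trans.P_frac[1] == (F(1, 3), F(1, 3), F(1, 3))

    def test_alternating_two_state_chain(self):
        trans = estimate_transitions([0, 1, 0, 1])
        assert trans.P_frac == ((F(0), F(1)), (F(1), F(0)))


def enumerate_kstep(P, k):
    """Path-enumeration oracle: sum the probability of every length-k path."""
    s = len(P)
    out = [[Fraction(0)] * s for _ in range(s)]
    for i in range(s):
        for path in itertools.product(range(s), repeat=k):
            prob = Fraction(1)
            prev = i
            for step in path:
                prob *= P[prev][step]
                prev = step
            out[i][path[-1]] += prob
    return tuple(tuple(row) for row in out)


class TestKStep:
    def test_michigan_two_step_matrix(self, michigan_chain):
        P2 = kstep(michigan_chain.transitions.P_frac, 2)
        assert P2 == (
            (F(1, 4), F(1, 2), F(1, 4)),
            (F(1, 2), F(1, 4), F(1, 4)),
            (F(1, 2), F(1, 2), F(0)),
        )

    def test_michigan_three_step_first_row(self, michigan_chain):
        P3 = kstep(michigan_chain.transitions.P_frac, 3)
        assert P3[0] == (F(3, 8), F(3, 8), F(1, 4))

    def test_one_step_is_identity_operation(self, michigan_chain):
        assert kstep(michigan_chain.transitions.P_frac, 1) == (
            michigan_chain.transitions.P_frac
        )

    @pytest.mark.parametrize("k", [1, 2, 3, 4])
    def test_agrees_with_path_enumeration(self, michigan_chain, k):
        P = michigan_chain.transitions.P_frac
        assert kstep(P, k) == enumerate_kstep(P, k)

    def test_chapman_kolmogorov_semigroup(self, michigan_chain):
        P = michigan_chain.transitions.P_frac
        from greycast.markov import _frac_matmul

        assert kstep(P, 5) == _frac_matmul(kstep(P, 2), kstep(P, 3))

    def test_powered_rows_sum_to_one(self, michigan_chain):
        for k in range(1, 5):
            for row in kstep(michigan_chain.transitions.P_frac, k):
                assert sum(row) == 1

    def test_bad_k(self, michigan_chain):
        with pytest.raises(ValueError):
            kstep(michigan_chain.transitions.P_frac, 0)


class TestFutureState:
    def test_michigan_summed_weights_and_modal_state(self, michigan_chain):
        weights, modal = future_state_distribution(
            MICHIGAN_STATES, michigan_chain.transitions, lookback=3
        )
        assert weights == (F(7, 8), F(9, 8), F(1))
        assert modal == 1  # S2

    def test_lookback_one_tie_breaks_to_lower_state(self, michigan_chain):
        with pytest.warns(UserWarning, match="tied"):
            weights, modal = future_state_distribution(
                MICHIGAN_STATES, michigan_chain.transitions, lookback=1
            )
        assert weights == (F(0), F(1, 2), F(1, 2))
        assert modal == 1  # S2 over S3

    def test_deterministic_chain_keeps_terminal_state(self):
        with pytest.warns(UserWarning, match="uniform"):
            ident = estimate_transitions([2, 2, 2, 2], s=3)
        weights, modal = future_state_distribution([2, 2, 2, 2], ident, 2)
        assert modal == 2
        assert weights[2] == 2

    def test_bad_lookback(self, michigan_chain):
        with pytest.raises(ValueError):
            future_state_distribution(MICHIGAN_STATES, michigan_chain.transitions, 0)
        with pytest.raises(ValueError):
            future_state_distribution([0, 1], michigan_chain.transitions, 3)


class TestCorrection:
    def test_michigan_corrected_improves_on_uncorrected(self, michigan, michigan_chain):
        actual = michigan.dependent_array
        mape_raw = np.mean(np.abs((actual - michigan_chain.fitted) / actual))
        mape_corr = np.mean(np.abs((actual - michigan_chain.corrected) / actual))
        assert mape_corr < mape_raw

    def test_final_year_correction_value(self, michigan_chain):
        # 1734 sits in S2; its midpoint lifts it to ~1762.2
        assert michigan_chain.corrected[-1] == pytest.approx(1762.2, abs=0.1)

    def test_zero_midpoint_leaves_fitted_unchanged(self):
        part = StatePartition(edges=np.array([-0.1, 0.1]))
        out = correct_fitted([100.0], [0], part)
        assert out[0] == 100.0

    def test_midpoint_residuals_recover_actuals_in_literal_mode(self):
        # residuals measured against the fitted value: if each relative error
        # sits exactly at its state midpoint, the correction is exact
        part = StatePartition(edges=np.array([0.0, 0.1, 0.2, 0.3]))
        mids = part.midpoints
        states = np.array([0, 2, 1, 0])
        fitted = np.array([100.0, 250.0, 400.0, 90.0])
        actual = fitted * (1 + mids[states])
        delta = residuals(actual, fitted, "fitted")
        np.testing.assert_allclose(delta, mids[states])
        corrected = correct_fitted(fitted, states, part)
        np.testing.assert_allclose(corrected, actual, rtol=1e-14)


class TestForecastCorrected:
    def test_michigan_next_year_value(self, michigan_chain):
        fc = michigan_chain.forecast(base_value=1730.0)
        assert round(fc) == 1758

    def test_symmetric_state_returns_base(self):
        assert forecast_corrected(1234.0, (-0.2, 0.2)) == 1234.0

    def test_plain_arithmetic(self):
        assert forecast_corrected(1000.0, (0.10, 0.20)) == pytest.approx(1150.0)
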