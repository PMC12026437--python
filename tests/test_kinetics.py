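import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from reference_values import FIT_GRID, PUBLISHED_SUM_R2, SELECTED_ORDERS, TEMPERATURES_C
from shelfkin import IndicatorSeries, KineticFit, aggregate_fits, fit_all_orders, fit_kinetic
from shelfkin.errors import (
    DegenerateDesignError,
    DomainError,
    InputError,
    InsufficientDataError,
    ModellingError,
)
from shelfkin.kinetics import back_transform, select_order, transform


class TestTransform:
    def test_order_1_log_of_powers_of_e(self):
        out = transform((1.0, math.e, math.e**2), 1)
        assert out == pytest.approx([0.0, 1.0, 2.0])

    def test_order_2_reciprocal(self):
        assert list(transform((2.0, 4.0), 2)) == [0.5, 0.25]

    def test_order_0_identity(self):
        values = (3.0, -1.0, 0.0)
        assert tuple(transform(values, 0)) == values

    def test_order_1_rejects_nonpositive(self):
        with pytest.raises(DomainError, match="index 1"):
            transform((1.0, -2.0), 1)

    def test_order_2_rejects_zero(self):
        with pytest.raises(DomainError):
            transform((1.0, 0.0), 2)

    @pytest.mark.parametrize("order", [0, 1, 2])
    def test_back_transform_inverts(self, order):
        values = np.array([0.5, 1.0, 2.5, 7.0])
        assert back_transform(transform(values, order), order) == pytest.approx(values)


class TestFitKinetic:
    def test_exact_zero_order_line(self, zero_order_series):
        fit = fit_kinetic(zero_order_series, 0)
        assert fit.k == pytest.approx(2.0, abs=1e-12)
        assert fit.intercept == pytest.approx(10.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.rmse == pytest.approx(0.0, abs=1e-9)

    def test_exact_first_order_decay(self, first_order_decay_series):
        fit = fit_kinetic(first_order_decay_series, 1)
        assert fit.k == pytest.approx(-0.3, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_constant_series_flat_fit(self):
        series = IndicatorSeries("AV", "", 4.0, (0, 1, 2), (5.0, 5.0, 5.0), "increasing")
        fit = fit_kinetic(series, 0)
        assert fit.k == pytest.approx(0.0, abs=1e-12)
        assert fit.rmse == pytest.approx(0.0, abs=1e-12)
        assert fit.r_squared == 1.0

    def test_too_few_points(self):
        series = IndicatorSeries("AV", "", 4.0, (0, 1), (1.0, 2.0), "increasing")
        with pytest.raises(InsufficientDataError):
            fit_kinetic(series, 0)

    def test_domain_error_names_time_point(self):
        series = IndicatorSeries("TVC", "", 4.0, (0, 1, 2), (1.0, -1.0, 2.0), "increasing")
        with pytest.raises(DomainError, match="t = 1"):
            fit_kinetic(series, 1)

    def test_forced_intercept_pins_line_to_initial_value(self):
        # noisy points but exact value at t=0; pinned line must pass through it
        series = IndicatorSeries("AV", "", 4.0, (0, 1, 2, 3), (1.0, 2.2, 2.8, 4.1), "increasing")
        fit = fit_kinetic(series, 0, force_intercept=True)
        assert fit.intercept == pytest.approx(1.0)
        free = fit_kinetic(series, 0)
        assert free.intercept != pytest.approx(1.0)

    def test_sign_of_k_follows_direction(self, first_order_decay_series):
        assert fit_kinetic(first_order_decay_series, 0).k < 0
        assert fit_kinetic(first_order_decay_series, 1).k < 0

    def test_rmse_is_in_original_units(self):
        # first-order fit of exact data: rmse must be 0 in original space too
        t = (0.0, 1.0, 2.0, 4.0)
        series = IndicatorSeries(
            "TVC", "", 4.0, t, tuple(2.0 * math.exp(0.5 * ti) for ti in t), "increasing"
        )
        fit = fit_kinetic(series, 1)
        assert fit.rmse == pytest.approx(0.0, abs=1e-9)


def normal_equations(t, y):
    """Independent OLS oracle: explicit normal-equation solve."""
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    design = np.array([[len(t), t.sum()], [t.sum(), (t**2).sum()]])
    rhs = np.array([y.sum(), (t * y).sum()])
    intercept, slope = np.linalg.solve(design, rhs)
    return slope, intercept


class TestOlsOracle:
    """Fitted slope/intercept must match independently coded normal equations."""

    @given(
        st.lists(
            st.floats(min_value=0.1, max_value=50.0, allow_nan=False),
            min_size=3, max_size=6,
        ),
        st.floats(min_value=-2.0, max_value=2.0),
        st.floats(min_value=0.5, max_value=20.0),
        st.floats(min_value=-1.0, max_value=1.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_zero_order_slope_matches_normal_equations(self, noise, slope, a0, drift):
        t = tuple(float(i) for i in range(len(noise)))
        values = tuple(a0 + slope * ti + drift * n / 50.0 for ti, n in zip(t, noise))
        if any(not math.isfinite(v) for v in values):
            return
        series = IndicatorSeries("TVB-N", "", 25.0, t, values, "increasing")
        fit = fit_kinetic(series, 0)
        exp_slope, exp_intercept = normal_equations(t, values)
        assert fit.k == pytest.approx(exp_slope, abs=1e-9)
        assert fit.intercept == pytest.approx(exp_intercept, abs=1e-9)

    def test_log_space_fit_matches_normal_equations(self, first_order_decay_series):
        fit = fit_kinetic(first_order_decay_series, 1)
        t = first_order_decay_series.times_days
        y = np.log(first_order_decay_series.values)
        exp_slope, exp_intercept = normal_equations(t, y)
        assert fit.k == pytest.approx(exp_slope, abs=1e-9)
        assert fit.intercept == pytest.approx(exp_intercept, abs=1e-9)


def _series_from_order(order, k, a0, temp, times=(0, 1, 2, 3, 4, 5)):
    times = tuple(float(t) for t in times)
    if order == 0:
        values = tuple(a0 + k * t for t in times)
    elif order == 1:
        values = tuple(a0 * math.exp(k * t) for t in times)
    else:
        values = tuple(1.0 / (1.0 / a0 + k * t) for t in times)
    return IndicatorSeries(
        "TVB-N", "", temp, times, values,
        "increasing" if k > 0 else "decreasing",
    )


class TestFitAllOrders:
    def test_noise_free_data_selects_generating_order(self):
        for order in (0, 1, 2):
            series = [
                _series_from_order(order, k, 5.0, temp)
                for temp, k in [(4, 0.05), (25, 0.1), (37, 0.2)]
            ]
            kinetics = fit_all_orders(series)
            assert kinetics.selected_order == order
            assert kinetics.sum_r_squared[order] == pytest.approx(3.0, abs=1e-9)

    def test_single_temperature_degenerate_sum(self):
        kinetics = fit_all_orders([_series_from_order(0, 0.5, 5.0, 25)])
        fit = kinetics.fit_for(25.0, 0)
        assert kinetics.sum_r_squared[0] == pytest.approx(fit.r_squared)

    def test_mixed_indicators_rejected(self, zero_order_series, first_order_decay_series):
        with pytest.raises(InputError, match="mixed"):
            fit_all_orders([zero_order_series, first_order_decay_series])

    def test_infeasible_order_excluded_and_flagged(self):
        # negative values make orders 1 and 2 undefined at one temperature
        good = _series_from_order(0, 0.5, 5.0, 4)
        crossing = IndicatorSeries(
            "TVB-N", "", 37.0, (0, 1, 2, 3), (2.0, 1.0, -0.5, -1.5), "decreasing"
        )
        kinetics = fit_all_orders([good, crossing])
        assert 1 in kinetics.infeasible
        assert 1 not in kinetics.sum_r_squared
        assert kinetics.selected_order == 0

    def test_no_feasible_order_raises(self):
        crossing = IndicatorSeries(
            "TVB-N", "", 37.0, (0, 1, 2), (2.0, 0.0, -1.0), "decreasing"
        )
        with pytest.raises(ModellingError):
            fit_all_orders([crossing], orders=(1, 2))

    def test_sum_invariant_to_temperature_order(self):
        series = [
            _series_from_order(0, k, 5.0, temp)
            for temp, k in [(4, 0.05), (25, 0.1), (37, 0.2)]
        ]
        forward = fit_all_orders(series)
        backward = fit_all_orders(series[::-1])
        assert forward.sum_r_squared == backward.sum_r_squared
        assert forward.selected_order == backward.selected_order


def _published_fits(indicator):
    """KineticFit records carrying the published R²/RMSE grid."""
    fits = []
    for order, (r2s, rmses) in FIT_GRID[indicator].items():
        for temp, r2, rmse in zip(TEMPERATURES_C, r2s, rmses):
            fits.append(
                KineticFit(
                    indicator=indicator, temperature_c=temp, order=order,
                    k=math.nan, intercept=math.nan, r_squared=r2, rmse=rmse,
                    n_points=6,
                )
            )
    return fits


class TestPublishedSelectionGrid:
    @pytest.mark.parametrize("indicator", list(FIT_GRID))
    def test_sum_r_squared_matches_published(self, indicator):
        kinetics = aggregate_fits(_published_fits(indicator))
        for order, expected in PUBLISHED_SUM_R2[indicator].items():
            assert kinetics.sum_r_squared[order] == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize("indicator,order", SELECTED_ORDERS.items())
    def test_selected_order_matches_published(self, indicator, order):
        assert aggregate_fits(_published_fits(indicator)).selected_order == order


class TestSelectOrder:
    def test_argmax_of_sums(self):
        assert select_order({0: 2.906, 1: 2.856, 2: 2.556}) == 0
        assert select_order({0: 2.916, 1: 2.958, 2: 2.919}) == 1

    def test_tie_broken_by_rmse_then_order(self):
        assert select_order({0: 2.9, 1: 2.9}, {0: 3.0, 1: 2.0}) == 1
        assert select_order({0: 2.9, 1: 2.9}, {0: 2.0, 1: 2.0}) == 0
        assert select_order({0: 2.9, 1: 2.9}) == 0

    def test_empty_raises(self):
        with pytest.raises(ModellingError):
            select_order({})
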