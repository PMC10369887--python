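"""Time-continuous density: correlations, temporal length scale, derivative."""

import warnings

import numpy as np
import pandas as pd
import pytest

from celldensity import (
    KernelSpec,
    TimeSeriesStates,
    fit_time_continuous,
    fit_time_length_scale,
    fit_timepoint_densities,
    predict_at_time,
)
from celldensity.containers import StateMatrix
from celldensity.kernels import matern52_cross, matern52_from_distance
from celldensity.timeseries import compute_time_correlations, density_time_derivative


def _two_timepoint_data(n=120, seed=0, shift=0.0):
    rng = np.random.default_rng(seed)
    X0 = rng.standard_normal((n, 2))
    X1 = rng.standard_normal((n, 2)) + shift
    states = StateMatrix(np.vstack([X0, X1]))
    times = np.concatenate([np.zeros(n), np.ones(n)])
    return TimeSeriesStates(states, times)


class TestTimeSeriesStates:
    def test_requires_two_distinct_timepoints(self):
        with pytest.raises(ValueError, match="distinct"):
            TimeSeriesStates(StateMatrix(np.zeros((4, 2)) + np.arange(4)[:, None]),
                             np.zeros(4))

    def test_requires_two_cells_per_timepoint(self):
        with pytest.raises(ValueError):
            TimeSeriesStates(
                StateMatrix(np.arange(6, dtype=float).reshape(3, 2)),
                np.array([0.0, 0.0, 1.0]),
            )


class TestFitTimepointDensities:
    def test_undersized_timepoint_skipped_with_warning(self):
        data = _two_timepoint_data(n=60)
        # add a third timepoint with only 10 cells
        rng = np.random.default_rng(1)
        extra = StateMatrix(
            np.vstack([data.states.coordinates, rng.standard_normal((10, 2))])
        )
        times = np.concatenate([data.timepoints, np.full(10, 2.0)])
        data3 = TimeSeriesStates(extra, times)
        with pytest.warns(UserWarning, match="excluded"):
            fits = fit_timepoint_densities(data3, min_cells=50)
        assert set(fits) == {0.0, 1.0}

    def test_undersized_timepoint_error_mode(self):
        data = _two_timepoint_data(n=30)
        with pytest.raises(ValueError):
            fit_timepoint_densities(data, min_cells=50, on_undersized="error")

    def test_identical_coordinates_give_agreeing_functions(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((80, 2))
        states = StateMatrix(np.vstack([X, X]))
        times = np.concatenate([np.zeros(80), np.ones(80)])
        data = TimeSeriesStates(states, times)
        fits = fit_timepoint_densities(data, min_cells=50)
        from scipy.stats import spearmanr

        r = spearmanr(fits[0.0].predict(X), fits[1.0].predict(X)).statistic
        assert r >= 0.999


class TestTimeCorrelations:
    def test_symmetric_unit_diagonal(self):
        data = _two_timepoint_data(shift=1.0)
        fits = fit_timepoint_densities(data, min_cells=50)
        P = compute_time_correlations(fits, data)
        np.testing.assert_allclose(P.to_numpy(), P.to_numpy().T)
        np.testing.assert_allclose(np.diag(P.to_numpy()), 1.0)

    def test_identical_functions_correlate_to_one(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((80, 2))
        states = StateMatrix(np.vstack([X, X]))
        data = TimeSeriesStates(states, np.repeat([0.0, 1.0], 80))
        fits = fit_timepoint_densities(data, min_cells=50)
        fits[1.0] = fits[0.0]  # literally the same function
        P = compute_time_correlations(fits, data)
        assert P.iloc[0, 1] == pytest.approx(1.0)

    def test_separated_mixtures_decorrelate(self):
        rng = np.random.default_rng(4)
        X0 = rng.standard_normal((100, 2))
        X1 = rng.standard_normal((100, 2)) + [0.5, 0.0]
        X2 = rng.standard_normal((100, 2)) + [30.0, 0.0]
        states = StateMatrix(np.vstack([X0, X1, X2]))
        data = TimeSeriesStates(states, np.repeat([0.0, 1.0, 2.0], 100))
        fits = fit_timepoint_densities(data, min_cells=50)
        P = compute_time_correlations(fits, data)
        assert P.loc[0.0, 2.0] < P.loc[0.0, 1.0]


class TestFitTimeLengthScale:
    def test_exact_self_consistent_recovery(self):
        times = np.array([0.0, 0.25, 0.5, 0.75, 1.0])
        dt = np.abs(times[:, None] - times[None, :])
        P = matern52_from_distance(dt, 0.5)
        lt = fit_time_length_scale(pd.DataFrame(P, index=times, columns=times))
        assert lt == pytest.approx(0.5, abs=1e-3)

    def test_flat_correlations_hit_upper_bound_with_warning(self):
        times = np.array([0.0, 1.0, 2.0])
        P = np.ones((3, 3))
        with pytest.warns(UserWarning, match="bound"):
            lt = fit_time_length_scale(P, times)
        assert lt >= 0.99 * 100 * 2.0

    def test_invariance_to_common_time_shift(self):
        times = np.array([0.0, 0.5, 1.0, 1.5])
        dt = np.abs(times[:, None] - times[None, :])
        P = matern52_from_distance(dt, 0.7)
        a = fit_time_length_scale(P, times)
        b = fit_time_length_scale(P, times + 123.0)
        assert a == pytest.approx(b, rel=1e-6)


class TestTimeContinuousModel:
    def test_product_kernel_reduces_to_state_kernel_at_equal_times(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((10, 3))
        spec = KernelSpec(length_scale=1.3)
        tspec = KernelSpec(length_scale=2.0)
        A = np.column_stack([X, np.full(10, 4.0)])
        Ks = matern52_cross(X, X, spec)
        Kt = matern52_cross(A[:, -1:], A[:, -1:], tspec)
        np.testing.assert_allclose(Ks * Kt, Ks)

    def test_deterministic_given_seed(self):
        data = _two_timepoint_data(shift=0.5)
        m1 = fit_time_continuous(data, 1.0, seed=3)
        m2 = fit_time_continuous(data, 1.0, seed=3)
        np.testing.assert_array_equal(
            m1.latent_coefficients, m2.latent_coefficients
        )

    def test_prediction_continuous_in_time(self):
        data = _two_timepoint_data(shift=1.0)
        model = fit_time_continuous(data, 1.0)
        q = data.states.coordinates[:5]
        ts = np.linspace(0, 1, 41)
        vals = np.array([predict_at_time(model, q, t) for t in ts])
        jumps = np.max(np.abs(np.diff(vals, axis=0)))
        ts2 = np.linspace(0, 1, 161)
        vals2 = np.array([predict_at_time(model, q, t) for t in ts2])
        jumps2 = np.max(np.abs(np.diff(vals2, axis=0)))
        assert jumps2 < jumps  # refinement shrinks the largest jump

    def test_extrapolation_warns(self):
        data = _two_timepoint_data()
        model = fit_time_continuous(data, 1.0)
        with pytest.warns(UserWarning, match="outside"):
            predict_at_time(model, data.states.coordinates[:3], 5.0)


class TestTimeDerivative:
    def test_analytic_matches_finite_difference(self):
        data = _two_timepoint_data(shift=1.5)
        model = fit_time_continuous(data, 0.7)
        q = data.states.coordinates[::40]
        ana = density_time_derivative(model, q, 0.5)
        fd = density_time_derivative(model, q, 0.5, method="fd")
        np.testing.assert_allclose(ana, fd, rtol=1e-4, atol=1e-8)

    def test_stationary_process_has_small_derivative(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((90, 2))
        jitter = rng.normal(scale=0.02, size=(3, 90, 2))
        states = StateMatrix(np.vstack([X + j for j in jitter]))
        data = TimeSeriesStates(states, np.repeat([0.0, 1.0, 2.0], 90))
        model = fit_time_continuous(data, 10.0)  # long time scale: stationary
        deriv = density_time_derivative(model, X[:20], 1.0)
        assert np.max(np.abs(deriv)) < 0.05

    def test_growing_mode_has_positive_derivative(self):
        # mass appears at +4 between t=0 and t=1: derivative positive there,
        # negative at the vanishing mode
        rng = np.random.default_rng(7)
        n = 150
        X0 = rng.standard_normal((n, 2))
        X1 = rng.standard_normal((n, 2)) + [4.0, 0.0]
        states = StateMatrix(np.vstack([X0, X1]))
        data = TimeSeriesStates(states, np.repeat([0.0, 1.0], n))
        model = fit_time_continuous(data, 0.5)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            d_new = density_time_derivative(model, np.array([[4.0, 0.0]]), 0.5)
            d_old = density_time_derivative(model, np.array([[0.0, 0.0]]), 0.5)
        assert d_new[0] > 0
        assert d_old[0] < 0
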