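"""Lag-logistic model: closed form, ODE equivalence and constrained fitting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from biofilmnet.growth import (
    LOG10K_BOUNDS,
    FitBounds,
    GrowthCurve,
    GrowthParams,
    InvalidParameterError,
    detect_growth,
    fit_growth,
    growth_ode_rhs,
    logistic_value,
)


def _random_params(rng):
    x0 = 10 ** rng.uniform(2, 5)
    k = x0 * 10 ** rng.uniform(0.5, 4)
    return GrowthParams(x0=x0, mu=rng.uniform(0.05, 1.5), K=k,
                        tau=rng.uniform(0, 40))


class TestLogisticValue:
    @pytest.mark.parametrize("t, p, expected", [
        # still in the lag phase: count equals the inoculum density
        (10.0, GrowthParams(1e4, 0.5, 1e7, 20.0), 1e4),
        # x0 = K is a fixed point of the logistic
        (50.0, GrowthParams(1e6, 0.5, 1e6, 0.0), 1e6),
    ])
    def test_fixed_values(self, t, p, expected):
        assert logistic_value(t, p) == pytest.approx(expected, rel=1e-12)

    def test_asymptote_reaches_carrying_capacity(self):
        p = GrowthParams(1e4, 0.5, 1e7, 20.0)
        assert logistic_value(1e3, p) == pytest.approx(1e7, rel=1e-9)

    def test_continuous_at_lag_end(self):
        p = GrowthParams(1e4, 0.9, 1e7, 33.0)
        eps = 1e-9
        assert logistic_value(p.tau - eps, p) == pytest.approx(
            logistic_value(p.tau + eps, p), rel=1e-6)

    def test_invalid_parameters_raise(self):
        with pytest.raises(InvalidParameterError):
            GrowthParams(-1.0, 0.5, 1e7, 0.0)
        with pytest.raises(InvalidParameterError):
            GrowthParams(1e4, -0.5, 1e7, 0.0)
        undefined = GrowthParams(1e4, math.nan, 1e7, math.nan)
        with pytest.raises(InvalidParameterError):
            logistic_value(10.0, undefined)

    def test_closed_form_matches_ode_integration(self):
        """Closed form agrees with high-order numerical integration of the
        piecewise ODE (lag, then logistic) to 1e-6 relative, over a
        randomized parameter grid plus the community P. fluorescens case."""
        rng = np.random.default_rng(42)
        cases = [_random_params(rng) for _ in range(100)]
        cases.append(GrowthParams(x0=2.7e4, mu=0.94, K=5.8e6, tau=33.0))
        for p in cases:
            t_end = p.tau + 8.0 / max(p.mu, 0.05)
            # integrate the logistic phase from the switch at tau; before
            # it the ODE solution is exactly x0
            sol = solve_ivp(growth_ode_rhs, (p.tau, t_end), [p.x0],
                            args=(p,), rtol=1e-10, atol=1e-6,
                            dense_output=True)
            ts = np.linspace(0, t_end, 13)
            numeric = np.where(ts < p.tau, p.x0,
                               sol.sol(np.maximum(ts, p.tau))[0])
            closed = logistic_value(ts, p)
            assert np.allclose(closed, numeric, rtol=1e-6)

    @given(st.floats(2, 5), st.floats(-2, 2), st.floats(0.05, 1.5),
           st.floats(0, 40))
    @settings(max_examples=60, deadline=None)
    def test_monotone_in_time(self, log_x0, log_ratio, mu, tau):
        x0 = 10 ** log_x0
        k = x0 * 10 ** log_ratio
        if abs(k - x0) < 1e-9:
            k = x0
        p = GrowthParams(x0=x0, mu=mu, K=k, tau=tau)
        ts = np.linspace(0, tau + 50, 80)
        vals = np.asarray(logistic_value(ts, p))
        diffs = np.diff(vals)
        if x0 < k:
            assert np.all(diffs >= -1e-6 * vals[:-1])
        elif x0 > k:
            assert np.all(diffs <= 1e-6 * vals[:-1])
        else:
            assert np.allclose(vals, x0)


class TestOdeRhs:
    @pytest.mark.parametrize("t, x, p, expected", [
        (5.0, 1e4, GrowthParams(1e4, 0.5, 1e7, 10.0), 0.0),       # latency
        (20.0, 1e7, GrowthParams(1e4, 0.5, 1e7, 10.0), 0.0),      # at capacity
        (20.0, 5e6, GrowthParams(1e4, 0.4, 1e7, 10.0), 0.1 * 1e7),
    ])
    def test_algebra(self, t, x, p, expected):
        assert growth_ode_rhs(t, x, p) == pytest.approx(expected, rel=1e-12)


class TestDetectGrowth:
    @pytest.mark.parametrize("counts, expected", [
        ((7.9e4, 8e4, 7e4, 9e4), False),       # roughly constant population
        ((1e4, 1e5, 1e6, 1e7), True),          # 3 log10 increase
        ((1e5, 1e5 * 10 ** 0.49), False),      # just below the 0.5 threshold
        ((1e5, 1e5 * 10 ** 0.51), True),
    ])
    def test_threshold(self, counts, expected):
        times = np.arange(len(counts), dtype=float) * 24
        curve = GrowthCurve(times, np.array(counts, dtype=float))
        assert detect_growth(curve) is expected

    def test_all_censored_errors(self):
        curve = GrowthCurve(np.array([0.0, 24.0]), np.array([1e3, 1e3]),
                            censored=[True, True])
        with pytest.raises(ValueError):
            detect_growth(curve)


class TestFitGrowth:
    def test_noiseless_recovery(self):
        """On noiseless identifiable data the generating parameters are the
        global optimum; the fitter recovers them to 1e-3 relative."""
        p = GrowthParams(x0=2.7e4, mu=0.94, K=5.8e6, tau=33.0)
        t = np.arange(0, 73, 6.0)
        res = fit_growth(GrowthCurve(t, logistic_value(t, p)))
        assert res.status == "fitted"
        assert res.params.mu == pytest.approx(p.mu, rel=1e-3)
        assert res.params.K == pytest.approx(p.K, rel=1e-3)
        assert res.params.tau == pytest.approx(p.tau, rel=1e-3)

    def test_flat_curve_no_growth_mean_capacity(self):
        """A flat population is not fitted; K is reported as the mean count
        and the rate/lag are undefined."""
        c = GrowthCurve(np.array([0, 24, 48, 72, 96.0]), np.full(5, 2.3e5))
        res = fit_growth(c)
        assert res.status == "no_growth"
        assert res.params.K == pytest.approx(2.3e5)
        assert math.isnan(res.params.mu) and math.isnan(res.params.tau)

    def test_censored_start_insufficient_data(self):
        """When early counts are below detection, x0 is unknown and the fit
        is inconclusive."""
        c = GrowthCurve(np.array([0, 24, 48, 72, 96.0]),
                        np.array([1e3, 1e3, 5e6, 8e6, 8.5e6]),
                        censored=[True, True, False, False, False])
        assert fit_growth(c).status == "insufficient_data"

    def test_too_few_points_insufficient(self):
        c = GrowthCurve(np.array([0, 24, 48.0]), np.array([1e4, 1e5, 1e6]))
        assert fit_growth(c).status == "insufficient_data"

    def test_empty_curve_errors(self):
        with pytest.raises(ValueError):
            GrowthCurve(np.array([]), np.array([]))

    def test_optimum_beats_grid_search(self):
        """The constrained optimum is at least as good as a brute-force
        20x20x20 grid over (mu, tau, log10 K)."""
        p = GrowthParams(x0=2.9e3, mu=0.25, K=8.3e6, tau=0.0)
        rng = np.random.default_rng(7)
        t = np.tile(np.arange(0, 73, 6.0), 3)
        counts = logistic_value(t, p) * 10 ** (0.1 * rng.standard_normal(t.size))
        curve = GrowthCurve(t, counts)
        bounds = FitBounds()
        res = fit_growth(curve, bounds)

        x0 = 10 ** np.log10(counts[t == 0]).mean()
        logx = np.log10(counts)
        best = np.inf
        for mu in np.linspace(0, bounds.mu_max, 20):
            for tau in np.linspace(0, bounds.tau_max, 20):
                for logk in np.linspace(*LOG10K_BOUNDS, 20):
                    k = 10 ** logk
                    model = np.where(
                        t < tau, x0,
                        k * x0 / (x0 + (k - x0) * np.exp(-mu * np.maximum(t - tau, 0))))
                    best = min(best, np.sum((np.log10(model) - logx) ** 2))
        assert res.sse <= best + 1e-9

    def test_recovery_under_noise(self):
        """Median relative error of mu-hat and log10 K-hat stays below 10%
        at sigma = 0.1 log10 noise, 5 pooled replicates, 13 time points."""
        p = GrowthParams(x0=2.9e3, mu=0.25, K=8.3e6, tau=0.0)
        rng = np.random.default_rng(123)
        times = np.tile(np.arange(0, 73, 6.0), 5)
        errs_mu, errs_k = [], []
        for _ in range(100):
            counts = logistic_value(times, p) * 10 ** (
                0.1 * rng.standard_normal(times.size))
            res = fit_growth(GrowthCurve(times, counts))
            errs_mu.append(abs(res.params.mu - p.mu) / p.mu)
            errs_k.append(abs(np.log10(res.params.K) - np.log10(p.K))
                          / np.log10(p.K))
        assert np.median(errs_mu) < 0.10
        assert np.median(errs_k) < 0.10
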