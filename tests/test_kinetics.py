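"""Kinetic model evaluation, ODE consistency, and constrained fitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from fermkin import kinetics
from fermkin.datasets import FermentationSeries
from fermkin.kinetics import (
    Constraint,
    GrowthParams,
    ProductParams,
    SubstrateParams,
    eval_growth,
    eval_product,
    eval_substrate,
    gof_metrics,
    ode_rhs,
)

PAPER_GROWTH = GrowthParams(a=0.04773, b=2.106, c=0.683, d=7.582)
PAPER_PRODUCT = ProductParams(p0=0.0, m=1.559, n=0.07135, a=0.04772, b=4.821, c=0.683)
PAPER_SUBSTRATE = SubstrateParams(s0=30.44, M=1.858, N=0.09254, a=0.0477, b=3.917, c=0.683)


class TestClosedForms:
    def test_growth_at_zero_is_a_plus_d(self):
        assert eval_growth(0.0, PAPER_GROWTH) == pytest.approx(
            PAPER_GROWTH.a + PAPER_GROWTH.d, abs=1e-12)

    def test_growth_asymptote_is_b_plus_d(self):
        assert eval_growth(1e3, PAPER_GROWTH) == pytest.approx(
            PAPER_GROWTH.b + PAPER_GROWTH.d, abs=1e-9)

    def test_growth_matches_observed_14h_count(self, table3):
        # closed form with the fitted coefficients vs the 14 h observation
        assert eval_growth(14.0, PAPER_GROWTH) == pytest.approx(
            table3.viable_lg[-1], abs=0.05)

    def test_product_at_zero(self):
        assert eval_product(0.0, PAPER_PRODUCT) == pytest.approx(
            PAPER_PRODUCT.p0 + PAPER_PRODUCT.m * PAPER_PRODUCT.a, abs=1e-12)

    def test_product_matches_observed_14h_lactate(self, table3):
        assert eval_product(14.0, PAPER_PRODUCT) == pytest.approx(
            table3.lactate[-1], abs=0.2)

    def test_product_constant_when_m_n_zero(self):
        p = ProductParams(p0=3.0, m=0.0, n=0.0, a=0.05, b=2.0, c=0.7)
        t = np.linspace(0, 14, 15)
        np.testing.assert_allclose(eval_product(t, p), 3.0, atol=1e-12)

    def test_substrate_at_zero(self):
        assert eval_substrate(0.0, PAPER_SUBSTRATE) == pytest.approx(
            PAPER_SUBSTRATE.s0 - PAPER_SUBSTRATE.M * PAPER_SUBSTRATE.a, abs=1e-12)

    def test_substrate_consumption_matches_observed_14h(self, table3):
        consumed = PAPER_SUBSTRATE.s0 - eval_substrate(14.0, PAPER_SUBSTRATE)
        assert consumed == pytest.approx(table3.glucose_consumed[-1], abs=0.2)

    def test_substrate_constant_when_M_N_zero(self):
        p = SubstrateParams(s0=30.0, M=0.0, N=0.0, a=0.05, b=2.0, c=0.7)
        np.testing.assert_allclose(eval_substrate(np.arange(15.0), p), 30.0, atol=1e-12)

    def test_denominator_domain_error(self):
        # a > b makes the denominator cross zero backwards in time
        with pytest.raises(ValueError, match="denominator"):
            kinetics.logistic_increment(-10.0, 5.0, 2.0, 0.7)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(a=st.floats(0.01, 0.5), binc=st.floats(0.01, 5.0),
           c=st.floats(0.05, 1.5), d=st.floats(0.0, 10.0))
    def test_growth_monotone_and_bounded(self, a, binc, c, d):
        p = GrowthParams(a=a, b=a + binc, c=c, d=d)
        t = np.linspace(0.0, 14.0, 40)
        x = eval_growth(t, p)
        assert np.all(np.diff(x) >= -1e-9)
        assert np.all(x <= p.b + p.d + 1e-9)


class TestOdeConsistency:
    def test_growth_closed_form_vs_integrator(self):
        p = PAPER_GROWTH
        sol = solve_ivp(lambda t, x: ode_rhs("growth", x[0], t, p), (0, 14), [p.a],
                        t_eval=np.linspace(0, 14, 30), rtol=1e-10, atol=1e-12)
        np.testing.assert_allclose(
            sol.y[0], eval_growth(sol.t, p) - p.d, atol=1e-6)

    @pytest.mark.parametrize("kind,params,evaluate,sign", [
        ("product", PAPER_PRODUCT, eval_product, 1.0),
        ("substrate", PAPER_SUBSTRATE, eval_substrate, 1.0),
    ])
    def test_rate_forms_integrate_to_closed_forms(self, kind, params, evaluate, sign):
        y0 = float(evaluate(0.0, params))
        sol = solve_ivp(lambda t, y: ode_rhs(kind, y[0], t, params), (0, 14), [y0],
                        t_eval=np.linspace(0, 14, 30), rtol=1e-10, atol=1e-12)
        np.testing.assert_allclose(sol.y[0], evaluate(sol.t, params), atol=1e-6)

    def test_carrying_capacity_is_stationary(self):
        assert ode_rhs("growth", PAPER_GROWTH.b, 0.0, PAPER_GROWTH) == 0.0
        assert ode_rhs("growth", 0.0, 0.0, PAPER_GROWTH) == 0.0


def _grid_min_sse(predict, y, axes):
    """Brute-force minimum SSE over a dense parameter grid."""
    grids = np.meshgrid(*axes, indexing="ij")
    flat = [g.ravel() for g in grids]
    best = np.inf
    for theta in zip(*flat):
        r = predict(theta) - y
        best = min(best, float(r @ r))
    return best


class TestFitGrowth:
    def test_noise_free_recovery(self):
        truth = GrowthParams(a=0.06, b=2.5, c=0.6, d=7.4)
        t = np.arange(0.0, 16.0, 2.0)
        series = FermentationSeries(time=t, viable_lg=eval_growth(t, truth),
                                    lactate=np.zeros_like(t),
                                    glucose_consumed=np.zeros_like(t))
        cons = {k: Constraint(getattr(truth, k), 0, np.inf) for k in "abcd"}
        fit = kinetics.fit_growth(series, cons)
        for k in "abcd":
            assert fit[k] == pytest.approx(getattr(truth, k), abs=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_beats_grid_oracle_on_small_series(self):
        truth = GrowthParams(a=0.08, b=2.0, c=0.7, d=7.5)
        t = np.array([0.0, 3.0, 6.0, 9.0, 12.0])
        rng = np.random.default_rng(7)
        y = eval_growth(t, truth) + rng.normal(0, 0.03, t.shape)
        series = FermentationSeries(time=t, viable_lg=y,
                                    lactate=np.zeros_like(t),
                                    glucose_consumed=np.zeros_like(t))
        fit = kinetics.fit_growth(series)
        axes = (np.linspace(0.01, 0.3, 20), np.linspace(1.0, 3.5, 20),
                np.linspace(0.2, 1.4, 20), np.linspace(7.0, 8.0, 20))
        grid_best = _grid_min_sse(
            lambda th: eval_growth(t, GrowthParams(*th)), y, axes)
        assert fit.sse <= grid_best + 1e-12

    def test_too_few_points_rejected(self):
        t = np.array([0.0, 2.0, 4.0, 6.0])
        with pytest.raises(ValueError, match="at least 5"):
            kinetics.fit_growth(FermentationSeries(
                time=t, viable_lg=np.full(4, 8.0), lactate=np.zeros(4),
                glucose_consumed=np.zeros(4)))


class TestFitProductSubstrate:
    def test_product_noise_free_recovery(self):
        truth = PAPER_PRODUCT
        t = np.arange(0.0, 16.0, 2.0)
        series = FermentationSeries(time=t, viable_lg=np.full_like(t, 8.0),
                                    lactate=eval_product(t, truth),
                                    glucose_consumed=np.zeros_like(t))
        cons = {
            "p0": Constraint(truth.p0, 0, np.inf),
            "a": Constraint(truth.a, truth.a, truth.a),
            "b": Constraint(truth.b, 2, 10),
            "c": Constraint(truth.c, truth.c, truth.c),
            "m": Constraint(truth.m), "n": Constraint(truth.n),
        }
        fit = kinetics.fit_product(series, cons)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-10)
        assert fit["m"] == pytest.approx(truth.m, abs=1e-6)
        assert fit["n"] == pytest.approx(truth.n, abs=1e-6)

    def test_product_beats_grid_oracle(self):
        truth = ProductParams(p0=0.2, m=1.2, n=0.06, a=0.05, b=4.0, c=0.7)
        t = np.array([0.0, 2.5, 5.0, 7.5, 10.0, 12.5])
        rng = np.random.default_rng(11)
        y = np.maximum(eval_product(t, truth) + rng.normal(0, 0.1, t.shape), 0.0)
        series = FermentationSeries(time=t, viable_lg=np.full_like(t, 8.0),
                                    lactate=y, glucose_consumed=np.zeros_like(t))
        cons = {
            "p0": Constraint(0.0, 0, np.inf),
            "a": Constraint(truth.a, truth.a, truth.a),
            "b": Constraint(2.0, 2, 10),
            "c": Constraint(truth.c, truth.c, truth.c),
            "m": Constraint(0.9), "n": Constraint(0.02),
        }
        fit = kinetics.fit_product(series, cons)
        axes = (np.linspace(0.0, 1.0, 12), np.linspace(2.0, 8.0, 16),
                np.linspace(0.5, 2.0, 16), np.linspace(0.0, 0.15, 12))
        grid_best = _grid_min_sse(
            lambda th: eval_product(t, ProductParams(
                p0=th[0], b=th[1], m=th[2], n=th[3], a=truth.a, c=truth.c)),
            y, axes)
        assert fit.sse <= grid_best + 1e-12

    def test_substrate_offset_invariance(self, table3):
        f1 = kinetics.fit_substrate(table3, initial_glucose=30.44)
        f2 = kinetics.fit_substrate(table3, initial_glucose=50.0)
        assert f2["s0"] - f1["s0"] == pytest.approx(50.0 - 30.44, abs=1e-8)
        for k in ("M", "N", "b"):
            assert f2[k] == pytest.approx(f1[k], abs=1e-8)
        assert f2.r_squared == pytest.approx(f1.r_squared, abs=1e-8)
        assert f2.rmse == pytest.approx(f1.rmse, abs=1e-8)

    def test_fixed_coefficients_not_counted_in_dfe(self, table3):
        fit = kinetics.fit_product(table3)
        # 6 coefficients, 2 fixed -> 4 free on 8 points
        assert fit.dfe == 4
        assert set(fit.free_names) == {"p0", "b", "m", "n"}
        assert fit.ci["a"] == (0.0477, 0.0477)


class TestGofMetrics:
    def test_perfect_fit(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        r2, rmse, sse = gof_metrics(y, y, 1)
        assert (r2, rmse, sse) == (1.0, 0.0, 0.0)

    def test_mean_model_scores_zero(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        r2, _, _ = gof_metrics(y, np.full_like(y, y.mean()), 1)
        assert r2 == pytest.approx(0.0, abs=1e-12)

    def test_paper_growth_rmse_convention(self, table3):
        # n=8, p=4 free coefficients: the printed RMSE follows n - p
        pred = eval_growth(table3.time, PAPER_GROWTH)
        r2, rmse, _ = gof_metrics(table3.viable_lg, pred, 4)
        assert rmse == pytest.approx(0.0156, abs=5e-4)
        assert r2 == pytest.approx(0.9998, abs=5e-4)

    def test_constant_observations_rejected(self):
        with pytest.raises(ValueError, match="SST"):
            gof_metrics(np.ones(5), np.ones(5), 1)


class TestConfidenceIntervals:
    def test_paper_c_interval_recovered(self, table3):
        fit = kinetics.fit_growth(table3)
        lo, hi = fit.ci["c"]
        # printed interval (0.6247, 0.7412)
        assert lo == pytest.approx(0.6247, abs=5e-3)
        assert hi == pytest.approx(0.7412, abs=5e-3)

    def test_zero_noise_interval_collapses(self):
        truth = GrowthParams(a=0.06, b=2.5, c=0.6, d=7.4)
        t = np.arange(0.0, 16.0, 2.0)
        series = FermentationSeries(time=t, viable_lg=eval_growth(t, truth),
                                    lactate=np.zeros_like(t),
                                    glucose_consumed=np.zeros_like(t))
        fit = kinetics.fit_growth(series)
        lo, hi = fit.ci["c"]
        assert hi - lo < 1e-4

    def test_width_monotone_in_level(self, table3):
        fit = kinetics.fit_growth(table3)
        w95 = np.diff(kinetics.confidence_intervals(fit, 0.95)["c"])[0]
        w68 = np.diff(kinetics.confidence_intervals(fit, 0.68)["c"])[0]
        assert w95 >= w68
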