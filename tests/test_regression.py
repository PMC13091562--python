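"""Regression fitters against closed-form, grid-search and simulation oracles."""

import numpy as np
import pytest

from anestherm.regression import (
    compare_decay_rates,
    compare_linear_fits,
    conditional_breakpoint_fit,
    fit_breakpoint,
    fit_linear,
    fit_one_phase_decay,
)
from anestherm.synthetic import decay_curve

# parameters of the reference emergence-latency decay and breakpoint models
DECAY = dict(amp=20.3e5, rate=0.27, plateau=-69.06)
BREAK = dict(b1=-307.47, b2=31.88, b3=60.48)


def piecewise(x, b1, b2, b3):
    return b1 * (x < b2) * (x - b2) + b3


class TestLinear:
    def test_recovers_reference_line_exactly(self):
        x = np.array([20.0, 25.0, 32.0, 36.0])
        y = 0.66 * x + 14.79
        fit = fit_linear(x, y)
        assert fit.slope == pytest.approx(0.66, abs=1e-10)
        assert fit.intercept == pytest.approx(14.79, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_two_points_interpolate_exactly(self):
        fit = fit_linear([0.0, 2.0], [1.0, 5.0])
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.r_squared == 1.0

    def test_matches_normal_equations_oracle(self, rng):
        x = rng.normal(size=50)
        y = 3.0 * x - 1.0 + rng.normal(size=50)
        fit = fit_linear(x, y)
        design = np.column_stack([x, np.ones_like(x)])
        slope, intercept = np.linalg.solve(design.T @ design, design.T @ y)
        assert fit.slope == pytest.approx(slope, abs=1e-10)
        assert fit.intercept == pytest.approx(intercept, abs=1e-10)

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError):
            fit_linear([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestOnePhaseDecay:
    def test_recovers_reference_curve_to_three_sig_figs(self):
        x = np.linspace(26.0, 36.0, 40)
        y = decay_curve(x, DECAY["amp"], DECAY["rate"], DECAY["plateau"])
        fit = fit_one_phase_decay(x, y)
        assert fit.converged
        assert fit.rate == pytest.approx(0.27, abs=5e-4)
        assert fit.plateau == pytest.approx(-69.06, abs=0.05)

    def test_constant_response_degenerates_gracefully(self):
        fit = fit_one_phase_decay([1.0, 2.0, 3.0, 4.0], [5.0, 5.0, 5.0, 5.0])
        assert fit.converged
        assert fit.rate == 0.0
        assert fit.amplitude == 0.0
        assert fit.plateau == pytest.approx(5.0)

    def test_beats_grid_search_oracle(self, rng):
        """The fitted SSE is no worse than a 50^3 grid over (A, k, C)."""
        x = np.linspace(26.0, 36.0, 30)
        y = decay_curve(x, DECAY["amp"], DECAY["rate"], DECAY["plateau"])
        y = y + rng.normal(0, 0.05 * np.ptp(y), size=x.size)
        fit = fit_one_phase_decay(x, y)
        a_grid = np.linspace(0.1 * DECAY["amp"], 3 * DECAY["amp"], 50)
        k_grid = np.linspace(0.05, 0.6, 50)
        c_grid = np.linspace(np.min(y) - np.ptp(y), np.max(y), 50)
        pred = a_grid[:, None, None, None] * np.exp(
            -k_grid[None, :, None, None] * x[None, None, None, :]
        ) + c_grid[None, None, :, None]
        grid_best = float(np.min(np.sum((pred - y) ** 2, axis=-1)))
        assert fit.sse <= grid_best + 1e-9

    def test_scale_consistency(self, rng):
        x = np.linspace(26.0, 36.0, 30)
        y = decay_curve(x, DECAY["amp"], DECAY["rate"], DECAY["plateau"])
        y = y + rng.normal(0, 10.0, size=x.size)
        c = 3.7
        f1, f2 = fit_one_phase_decay(x, y), fit_one_phase_decay(x, c * y)
        assert f2.rate == pytest.approx(f1.rate, rel=1e-5)
        assert f2.amplitude == pytest.approx(c * f1.amplitude, rel=1e-4)
        assert f2.plateau == pytest.approx(c * f1.plateau, rel=1e-4)
        assert f2.r_squared == pytest.approx(f1.r_squared, abs=1e-8)


class TestBreakpoint:
    def test_recovers_reference_breakpoint(self):
        x = np.arange(26.0, 36.01, 0.5)
        y = piecewise(x, **BREAK)
        fit = fit_breakpoint(x, y)
        assert fit.identifiable
        assert fit.b2 == pytest.approx(31.88, abs=0.02)
        assert fit.b1 == pytest.approx(-307.47, abs=0.5)
        assert fit.b3 == pytest.approx(60.48, abs=0.5)

    def test_flat_response_is_unidentifiable(self):
        x = np.linspace(26.0, 36.0, 15)
        fit = fit_breakpoint(x, np.full(x.size, 60.48))
        assert not fit.identifiable
        assert np.isnan(fit.b2)
        assert fit.b3 == pytest.approx(60.48)

    def test_profile_sse_not_beaten_by_any_grid_candidate(self, rng):
        x = np.linspace(26.0, 36.0, 25)
        y = piecewise(x, **BREAK) + rng.normal(0, 30.0, size=x.size)
        fit = fit_breakpoint(x, y)
        xs = np.sort(x)
        for b2 in np.arange(xs[1] + 0.01, xs[-2], 0.01):
            assert fit.sse <= conditional_breakpoint_fit(x, y, b2)[2] + 1e-9

    def test_reduces_to_linear_fit_when_break_beyond_data(self, rng):
        x = np.linspace(26.0, 36.0, 20)
        y = -5.0 * x + 200.0 + rng.normal(0, 1.0, size=x.size)
        b2 = np.nextafter(x.max(), np.inf)  # every point on the sloped side
        b1, b3, sse = conditional_breakpoint_fit(x, y, b2)
        lf = fit_linear(x, y)
        assert b1 == pytest.approx(lf.slope, abs=1e-9)
        assert b3 - b1 * b2 == pytest.approx(lf.intercept, abs=1e-7)
        assert sse == pytest.approx(lf.sse, abs=1e-9)

    def test_scale_consistency(self, rng):
        x = np.linspace(26.0, 36.0, 25)
        y = piecewise(x, **BREAK) + rng.normal(0, 20.0, size=x.size)
        c = 2.5
        f1, f2 = fit_breakpoint(x, y), fit_breakpoint(x, c * y)
        assert f2.b2 == pytest.approx(f1.b2, abs=1e-3)
        assert f2.b1 == pytest.approx(c * f1.b1, rel=1e-4)
        assert f2.b3 == pytest.approx(c * f1.b3, rel=1e-4)


class TestCompareLinearFits:
    def test_identical_groups_give_f_zero_p_one(self, rng):
        x = rng.uniform(28, 36, 20)
        y = -4.0 * x + 170.0 + rng.normal(0, 2, 20)
        slope_test, int_test = compare_linear_fits((x, y), (x, y))
        assert slope_test.statistic == pytest.approx(0.0, abs=1e-9)
        assert slope_test.p_value == pytest.approx(1.0, abs=1e-5)
        assert int_test.statistic == pytest.approx(0.0, abs=1e-9)
        assert int_test.p_value == pytest.approx(1.0, abs=1e-5)

    def test_parallel_lines_with_offset_detected(self):
        """Parallel simulated lines: slope test stays null, intercept test
        rejects, with power > 0.99 over 500 replicates."""
        rng = np.random.default_rng(7)
        n = 200
        hits_slope, hits_int = 0, 0
        for _ in range(500):
            x1, x2 = rng.uniform(28, 36, n), rng.uniform(28, 36, n)
            y1 = -4.0 * x1 + 170.0 + rng.normal(0, 1.0, n)
            y2 = -4.0 * x2 + 172.0 + rng.normal(0, 1.0, n)
            s_t, i_t = compare_linear_fits((x1, y1), (x2, y2))
            hits_slope += s_t.p_value > 0.05
            hits_int += i_t.p_value < 0.001
        assert hits_slope / 500 > 0.9  # slope test keeps its nominal level
        assert hits_int / 500 > 0.99

    def test_f_statistic_matches_independent_nested_sse(self, rng):
        """F recomputed from per-group OLS residuals and the pooled
        common-slope estimator agrees to 1e-10."""
        x1, x2 = rng.uniform(20, 36, 15), rng.uniform(20, 36, 18)
        y1 = 0.7 * x1 + 10 + rng.normal(0, 1, 15)
        y2 = 0.5 * x2 + 12 + rng.normal(0, 1, 18)
        slope_test, _ = compare_linear_fits((x1, y1), (x2, y2))
        # full model = independent per-group OLS
        sse_full = fit_linear(x1, y1).sse + fit_linear(x2, y2).sse
        # common slope via pooled within-group covariance
        s_xy = np.sum((x1 - x1.mean()) * (y1 - y1.mean())) + np.sum(
            (x2 - x2.mean()) * (y2 - y2.mean())
        )
        s_xx = np.sum((x1 - x1.mean()) ** 2) + np.sum((x2 - x2.mean()) ** 2)
        b = s_xy / s_xx
        sse_cs = np.sum((y1 - y1.mean() - b * (x1 - x1.mean())) ** 2) + np.sum(
            (y2 - y2.mean() - b * (x2 - x2.mean())) ** 2
        )
        n = x1.size + x2.size
        f_oracle = (sse_cs - sse_full) / (sse_full / (n - 4))
        assert slope_test.statistic == pytest.approx(f_oracle, abs=1e-10)


class TestCompareDecayRates:
    def test_identical_groups_accept_shared_rate(self, rng):
        x = np.linspace(26, 36, 30)
        y = decay_curve(x, DECAY["amp"], DECAY["rate"], DECAY["plateau"]) + rng.normal(0, 20, 30)
        res = compare_decay_rates((x, y), (x, y))
        assert res.converged
        assert res.statistic == pytest.approx(0.0, abs=1e-6)
        assert res.p_value > 0.999

    def test_distinct_rates_detected(self):
        """k = 0.27 vs k = 0.14 groups, n = 50 each, 5 % noise: the shared-k
        test rejects in > 90 % of 200 replicates."""
        rng = np.random.default_rng(11)
        x = np.linspace(26.0, 36.0, 50)
        mu_a = decay_curve(x, 20.3e5, 0.27, -69.06)
        mu_b = decay_curve(x, 0.4e5, 0.14, -329.1)
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            ya = mu_a + rng.normal(0, 0.05 * np.ptp(mu_a), x.size)
            yb = mu_b + rng.normal(0, 0.05 * np.ptp(mu_b), x.size)
            res = compare_decay_rates((x, ya), (x, yb))
            hits += res.converged and res.p_value < 0.05
        assert hits / n_rep > 0.9

    def test_shared_rate_sse_never_below_separate(self, rng):
        for _ in range(5):
            x = np.linspace(26, 36, 25)
            ya = decay_curve(x, 1e5, 0.2, 10.0) + rng.normal(0, 15, 25)
            yb = decay_curve(x, 2e5, 0.3, -50.0) + rng.normal(0, 15, 25)
            fa, fb = fit_one_phase_decay(x, ya), fit_one_phase_decay(x, yb)
            res = compare_decay_rates((x, ya), (x, yb))
            # F >= 0 is exactly the nested inequality SSE_shared >= SSE_separate
            assert res.statistic >= 0.0
            assert fa.converged and fb.converged
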