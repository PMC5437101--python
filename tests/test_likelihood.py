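"""Composite likelihood, profiling, model selection and bootstrap."""

import math

import numpy as np
import pytest

from tempdiff import (CoalescentConfig, JointSFS, ScaledParams, aic,
                      anscombe_residuals, bootstrap_ci, build_timeline,
                      exact_small_sfs, fit_model, lrt, model_spectrum,
                      optimal_theta, poisson_loglik)


def _wrap(values):
    """Pad a vector of unmasked values with masked corners."""
    data = np.concatenate([[0.0], np.asarray(values, float), [0.0]])
    return JointSFS(data)


class TestPoissonLoglik:
    def test_single_cell_arithmetic(self):
        # S = 2, M = 2: 2*ln2 - 2 - ln(2!) = ln2 - 2
        ll = poisson_loglik(_wrap([2.0]), _wrap([2.0]))
        assert ll == pytest.approx(2 * math.log(2) - 2 - math.log(2))
        assert ll == pytest.approx(-1.3069, abs=1e-4)

    def test_maximized_cellwise_at_m_equals_s(self):
        S = _wrap([3.0, 7.0, 1.0])
        base = poisson_loglik(_wrap([3.0, 7.0, 1.0]), S)
        rng = np.random.default_rng(3)
        for _ in range(20):
            other = _wrap(np.array([3.0, 7.0, 1.0]) * rng.uniform(0.3, 3.0, 3))
            assert poisson_loglik(other, S) <= base + 1e-12

    def test_all_zero_data_gives_minus_total_mass(self):
        S = _wrap([0.0, 0.0])
        M = _wrap([4.0, 2.5])
        assert poisson_loglik(M, S) == pytest.approx(-6.5)

    def test_zero_model_with_observed_count_is_minus_inf(self):
        assert poisson_loglik(_wrap([0.0]), _wrap([3.0])) == -math.inf

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            poisson_loglik(_wrap([1.0]), _wrap([1.0, 2.0]))


class TestOptimalTheta:
    def test_proportional_data_recovers_factor(self):
        shape = _wrap([2.0, 1.0, 0.5])
        data = _wrap([6.0, 3.0, 1.5])
        assert optimal_theta(shape, data) == pytest.approx(3.0)

    def test_all_zero_data_gives_zero(self):
        assert optimal_theta(_wrap([1.0, 1.0]), _wrap([0.0, 0.0])) == 0.0

    def test_matches_numerical_grid_search(self):
        rng = np.random.default_rng(7)
        shape = _wrap(rng.uniform(0.1, 2.0, 5))
        data = _wrap(rng.poisson(50, 5).astype(float))
        closed = optimal_theta(shape, data)
        grid = np.linspace(max(closed * 0.5, 1e-3), closed * 1.5, 20001)
        lls = [poisson_loglik(JointSFS(shape.data * t, shape.mask.copy()), data)
               for t in grid]
        assert grid[int(np.argmax(lls))] == pytest.approx(closed, rel=1e-4)

    def test_zero_model_mass_rejected(self):
        with pytest.raises(ValueError):
            optimal_theta(_wrap([0.0, 0.0]), _wrap([1.0, 1.0]))


class TestLrt:
    def test_zero_statistic_gives_p_one(self):
        assert lrt(-100.0, -100.0, df=2) == pytest.approx(1.0)

    @pytest.mark.parametrize("stat,df,expected", [
        (9.21, 2, 0.01),       # chi-square(2) upper 1% point
        (3.841, 1, 0.05),      # chi-square(1) upper 5% point
    ])
    def test_chi_square_quantiles(self, stat, df, expected):
        assert lrt(0.0, stat / 2.0, df=df) == pytest.approx(expected, rel=1e-2)

    def test_negative_statistic_beyond_tolerance_rejected(self):
        with pytest.raises(ValueError):
            lrt(-10.0, -11.0, df=1)


class TestAic:
    def test_arithmetic(self):
        assert aic(-100.0, 3) == 206.0

    def test_more_parameters_at_equal_likelihood_cost_more(self):
        assert aic(-50.0, 4) > aic(-50.0, 3)

    def test_ranking_invariant_to_loglik_shift(self):
        lls = [-120.0, -118.5, -117.9]
        ks = [2, 4, 6]
        base = np.argsort([aic(ll, k) for ll, k in zip(lls, ks)])
        shifted = np.argsort([aic(ll + 55.5, k) for ll, k in zip(lls, ks)])
        np.testing.assert_array_equal(base, shifted)


class TestAnscombeResiduals:
    def test_zero_when_model_equals_data(self):
        r = anscombe_residuals(_wrap([4.0, 2.0]), _wrap([4.0, 2.0]))
        np.testing.assert_allclose(r[1:3], 0.0)

    def test_zero_observed_unit_expected(self):
        r = anscombe_residuals(_wrap([1.0]), _wrap([0.0]))
        assert r[1] == pytest.approx(-1.5)

    def test_sign_follows_data_minus_model(self):
        r = anscombe_residuals(_wrap([2.0, 2.0]), _wrap([3.0, 1.0]))
        assert r[1] > 0 > r[2]

    def test_zero_model_cells_are_nan_not_dropped(self):
        r = anscombe_residuals(_wrap([0.0, 1.0]), _wrap([1.0, 1.0]))
        assert math.isnan(r[1]) and not math.isnan(r[2])


def _poisson_data(shape_sfs, theta, seed):
    rng = np.random.default_rng(seed)
    expected = np.where(shape_sfs.mask, 0.0, shape_sfs.data * theta)
    return JointSFS(rng.poisson(expected).astype(float), shape_sfs.mask.copy())


class TestFitModel:
    def test_identical_seed_gives_identical_result(self, neutral_timeline):
        shape = exact_small_sfs(neutral_timeline, 6, 0)
        data = _poisson_data(shape, 2000.0, seed=1)
        cfg = CoalescentConfig(replicates=5_000, seed=42)
        a = fit_model("two_epoch", data, cfg=cfg, engine="exact",
                      fatol=1e-4, maxfev=300)
        b = fit_model("two_epoch", data, cfg=cfg, engine="exact",
                      fatol=1e-4, maxfev=300)
        assert a.loglik == b.loglik
        assert a.params == b.params

    def test_null_data_not_significant_under_two_epoch(self, neutral_timeline):
        shape = exact_small_sfs(neutral_timeline, 6, 0)
        data = _poisson_data(shape, 2000.0, seed=2)
        f0 = fit_model("neutral", data, engine="exact")
        f1 = fit_model("two_epoch", data, engine="exact", fatol=1e-6)
        p = lrt(f0.loglik, f1.loglik, df=2)
        assert p > 0.05

    def test_lrt_never_anticonservative_under_the_null(self, neutral_timeline):
        """The chi-square-referenced LRT on a ridge-degenerate nesting
        (neutral inside two-epoch) is a valid, conservative test: its
        rejection rate under the null stays at or below nominal."""
        shape = exact_small_sfs(neutral_timeline, 6, 0)
        expected = np.where(shape.mask, 0.0, shape.data * 2_000.0)
        rng = np.random.default_rng(17)
        starts = [dict(nu=0.3, tau=0.03), dict(nu=3.0, tau=0.3)]
        rejections = 0
        n_sims = 120
        for _ in range(n_sims):
            data = JointSFS(rng.poisson(expected).astype(float),
                            shape.mask.copy())
            f0 = fit_model("neutral", data, engine="exact")
            f1 = fit_model("two_epoch", data, engine="exact", starts=starts,
                           fatol=1e-4, maxfev=400)
            rejections += lrt(f0.loglik, f1.loglik, df=2) < 0.05
        rate = rejections / n_sims
        assert rate <= 0.05 + 3 * math.sqrt(0.05 * 0.95 / n_sims)

    def test_two_epoch_parameter_recovery(self):
        # strong contraction leaves a recoverable SFS signature
        truth = ScaledParams("two_epoch", dict(nu=0.2, tau=0.1))
        shape = exact_small_sfs(build_timeline(truth), 6, 0)
        data = _poisson_data(shape, 50_000.0, seed=3)
        fit = fit_model("two_epoch", data, engine="exact", fatol=1e-8,
                        starts=[dict(nu=0.05, tau=0.03), dict(nu=0.5, tau=0.3)])
        assert fit.params["nu"] == pytest.approx(0.2, rel=0.2)
        assert fit.theta == pytest.approx(50_000.0, rel=0.1)

    def test_free_fixed_partition_validated(self, neutral_timeline):
        shape = exact_small_sfs(neutral_timeline, 4, 0)
        data = _poisson_data(shape, 100.0, seed=4)
        with pytest.raises(ValueError, match="neither free nor fixed"):
            fit_model("two_epoch", data, free=("nu",), engine="exact")
        with pytest.raises(ValueError, match="unknown parameters"):
            fit_model("two_epoch", data, free=("nu", "bogus"),
                      fixed={"tau": 0.1}, engine="exact")

    def test_single_start_rejected(self, neutral_timeline):
        shape = exact_small_sfs(neutral_timeline, 4, 0)
        data = _poisson_data(shape, 100.0, seed=5)
        with pytest.raises(ValueError, match="two starts"):
            fit_model("two_epoch", data, starts=[dict(nu=1.0, tau=0.1)],
                      engine="exact")

    def test_profiled_theta_agrees_with_scan_inside_fit(self, neutral_timeline):
        shape = exact_small_sfs(neutral_timeline, 5, 0)
        data = _poisson_data(shape, 900.0, seed=6)
        fit = fit_model("neutral", data, engine="exact")
        assert fit.theta == pytest.approx(optimal_theta(shape, data), rel=1e-12)
        assert fit.aic == pytest.approx(-2 * fit.loglik)


class TestBootstrap:
    def test_zero_replicates_is_empty(self, neutral_timeline):
        shape = exact_small_sfs(neutral_timeline, 5, 0)
        data = _poisson_data(shape, 500.0, seed=7)
        fit = fit_model("neutral", data, engine="exact")
        assert bootstrap_ci("neutral", fit, data, 0) == {}

    def test_fixed_seed_reproduces_intervals(self, neutral_timeline):
        shape = exact_small_sfs(neutral_timeline, 5, 0)
        data = _poisson_data(shape, 500.0, seed=8)
        fit = fit_model("two_epoch", data, engine="exact", fatol=1e-4)
        kw = dict(cfg=CoalescentConfig(replicates=100, seed=1), seed=9)
        a = bootstrap_ci("two_epoch", fit, data, 8, **kw)
        b = bootstrap_ci("two_epoch", fit, data, 8, **kw)
        assert a == b

    def test_intervals_cover_truth_under_correct_model(self, neutral_timeline):
        shape = exact_small_sfs(neutral_timeline, 6, 0)
        data = _poisson_data(shape, 3000.0, seed=10)
        fit = fit_model("neutral", data, engine="exact")
        ci = bootstrap_ci("neutral", fit, data, 30, seed=11)
        lo, hi = ci["theta"]
        assert lo <= 3000.0 * 1.1 and hi >= 3000.0 * 0.9
        assert lo <= fit.theta <= hi
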