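"""EM estimation: likelihood, M-step, convergence and recovery."""

import numpy as np
import pytest

import regmixsim as rm
from regmixsim.em import MixtureParams

from conftest import random_dataset


def _point_dataset(x, y):
    return rm.Dataset(
        X=np.atleast_2d(np.asarray(x, dtype=float)).reshape(len(y), -1),
        y=np.asarray(y, dtype=float),
        true_class=np.ones(len(y), dtype=np.int64),
        seed=0,
    )


class TestLogLikelihood:
    def test_standard_normal_point(self):
        params = MixtureParams(
            coefficients=np.array([[0.0, 0.0]]),
            residual_variances=np.array([1.0]),
            proportions=np.array([1.0]),
        )
        data = _point_dataset([0.0], [0.0])
        assert rm.log_likelihood(params, data) == pytest.approx(-0.9189385, abs=1e-6)

    def test_mixture_collapse_to_single_component(self):
        rng = np.random.default_rng(0)
        data = random_dataset(rng, n=40)
        coef = np.array([[0.3, -0.5]])
        one = MixtureParams(
            coefficients=coef, residual_variances=np.array([0.8]), proportions=np.array([1.0])
        )
        two = MixtureParams(
            coefficients=np.vstack([coef, coef]),
            residual_variances=np.array([0.8, 0.8]),
            proportions=np.array([0.3, 0.7]),
        )
        assert rm.log_likelihood(two, data) == pytest.approx(rm.log_likelihood(one, data))

    def test_matches_bruteforce_summation(self):
        """Oracle: direct per-point density sums without log-space tricks."""
        rng = np.random.default_rng(4)
        data = random_dataset(rng, n=6)
        params = MixtureParams(
            coefficients=np.array([[0.1, 0.9], [-0.4, 0.2]]),
            residual_variances=np.array([0.5, 1.7]),
            proportions=np.array([0.35, 0.65]),
        )
        total = 0.0
        for i in range(6):
            dens = 0.0
            for k in range(2):
                mu = params.coefficients[k, 0] + params.coefficients[k, 1] * data.X[i, 0]
                s2 = params.residual_variances[k]
                dens += (
                    params.proportions[k]
                    * np.exp(-((data.y[i] - mu) ** 2) / (2 * s2))
                    / np.sqrt(2 * np.pi * s2)
                )
            total += np.log(dens)
        assert rm.log_likelihood(params, data) == pytest.approx(total, rel=1e-12)

    def test_nonpositive_variance_rejected(self, small_dataset):
        with pytest.raises(ValueError):
            MixtureParams(
                coefficients=np.array([[0.0, 0.0]]),
                residual_variances=np.array([0.0]),
                proportions=np.array([1.0]),
            )


class TestMStep:
    def test_hard_single_class_gives_ols_and_degenerate_other(self, small_dataset):
        n = small_dataset.n
        r = np.column_stack([np.ones(n), np.zeros(n)])
        params = rm.m_step(small_dataset, r, constrained=False)
        Xt = np.column_stack([np.ones(n), small_dataset.X])
        beta, *_ = np.linalg.lstsq(Xt, small_dataset.y, rcond=None)
        assert params.coefficients[0] == pytest.approx(beta, abs=1e-10)
        assert params.degenerate_classes == (1,)

    def test_constrained_pools_residual_sums(self):
        rng = np.random.default_rng(9)
        n = 30
        X = rng.standard_normal((n, 1))
        y = rng.standard_normal(n)
        data = rm.Dataset(X=X, y=y, true_class=np.ones(n, dtype=np.int64), seed=0)
        labels = np.repeat([0, 1], [12, 18])
        r = np.zeros((n, 2))
        r[np.arange(n), labels] = 1.0
        params = rm.m_step(data, r, constrained=True)
        sse = 0.0
        for k in range(2):
            mask = labels == k
            Xt = np.column_stack([np.ones(mask.sum()), X[mask]])
            beta, *_ = np.linalg.lstsq(Xt, y[mask], rcond=None)
            sse += float(((y[mask] - Xt @ beta) ** 2).sum())
        assert params.residual_variances[0] == pytest.approx(sse / n)
        assert params.residual_variances[1] == params.residual_variances[0]

    def test_proportions_are_mean_responsibilities(self, small_dataset):
        rng = np.random.default_rng(2)
        g = rng.dirichlet(np.ones(2), size=small_dataset.n)
        params = rm.m_step(small_dataset, g, constrained=False)
        assert params.proportions == pytest.approx(g.mean(axis=0))


class TestEmFit:
    def test_k1_equals_closed_form_ols(self, small_dataset):
        fit = rm.em_fit(small_dataset, K=1, constrained=False)
        n = small_dataset.n
        Xt = np.column_stack([np.ones(n), small_dataset.X])
        beta, *_ = np.linalg.lstsq(Xt, small_dataset.y, rcond=None)
        sse = float(((small_dataset.y - Xt @ beta) ** 2).sum())
        assert fit.converged
        assert fit.params.coefficients[0] == pytest.approx(beta, abs=1e-8)
        assert fit.params.residual_variances[0] == pytest.approx(sse / n, abs=1e-8)

    def test_parameter_recovery_large_separation(self):
        cond = rm.make_condition("single_intdiff1", "large", 5000)
        data = rm.generate_dataset(cond, 77)
        fit = rm.em_fit(data, K=2, constrained=False, config=rm.FitConfig(seed=3))
        fit = rm.align_labels(fit, cond)
        assert fit.converged
        n_k = np.bincount(data.true_class)[1:]
        # 3 MC SEs from the class-conditional OLS sampling variance
        se_slope = 3 * np.sqrt(np.array([0.51, 0.96]) / n_k)
        est_slopes = fit.params.coefficients[:, 1]
        assert abs(est_slopes[0] - 0.7) < 3 * se_slope[0] + 0.05
        assert abs(est_slopes[1] - 0.2) < 3 * se_slope[1] + 0.05
        assert abs(fit.params.coefficients[0, 0] - 1.0) < 0.1
        assert abs(fit.params.coefficients[1, 0] - 0.0) < 0.1

    def test_monotone_loglik_within_start(self, cond_single_large):
        data = rm.generate_dataset(cond_single_large, 5)
        config = rm.FitConfig(n_starts=4, n_hard_starts=1, seed=1, record_paths=True,
                              compute_se=False)
        fit = rm.em_fit(data, K=2, constrained=False, config=config)
        assert fit.loglik_paths
        for path in fit.loglik_paths:
            assert (np.diff(path) >= -1e-7 * np.abs(path[:-1])).all()

    def test_constrained_nested_in_free(self, light_config, cond_single_large):
        data = rm.generate_dataset(cond_single_large, 31)
        fits = rm.fit_both_variants(data, K=2, config_free=light_config,
                                    config_constrained=light_config)
        free, cons = fits["free"], fits["constrained"]
        assert free.converged and cons.converged
        assert cons.loglik <= free.loglik + 1e-6 * abs(free.loglik)
        assert len(set(np.round(cons.params.residual_variances, 12))) == 1

    def test_posterior_rows_sum_to_one(self, light_config, cond_two_large):
        data = rm.generate_dataset(cond_two_large, 17)
        fit = rm.em_fit(data, K=2, constrained=False, config=light_config)
        assert fit.converged
        assert fit.posteriors.sum(axis=1) == pytest.approx(np.ones(data.n), abs=1e-8)
        assert np.isfinite(fit.loglik)
        assert (fit.standard_errors["coefficients"] > 0).all()

    def test_infeasible_inputs_raise(self, small_dataset):
        tiny = rm.Dataset(
            X=small_dataset.X[:5], y=small_dataset.y[:5],
            true_class=small_dataset.true_class[:5], seed=0,
        )
        with pytest.raises(ValueError):
            rm.em_fit(tiny, K=2, constrained=False)
        with pytest.raises(ValueError):
            rm.em_fit(small_dataset, K=0, constrained=False)
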