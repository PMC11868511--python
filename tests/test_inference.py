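"""Tests of beta-binomial likelihood evaluation, fitting, and GOF."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.stats import kstest

from dcvwalk.distributions import bb_log_pmf, bb_pmf
from dcvwalk.inference import (
    DisplacementSample,
    FitResult,
    bb_neg_loglik,
    chi_square_binned,
    fit_joint,
    fit_mle,
    gof_summary,
    mom_init,
)
from dcvwalk.params import ModelParams
from dcvwalk.simulate import sample_displacement_steps


def _sample(params, n, size, seed, **kw):
    k = sample_displacement_steps(n, params, size, seed=seed)
    return DisplacementSample(k_values=k, n_trials=n, **kw)


class TestNegLoglik:
    def test_single_bernoulli_observation(self):
        s = DisplacementSample(k_values=[1], n_trials=1)
        assert bb_neg_loglik(s, (1.0, 1.0)) == pytest.approx(np.log(2))

    def test_empty_sample_contributes_nothing(self):
        s = DisplacementSample(k_values=[], n_trials=5)
        assert bb_neg_loglik(s, (2.0, 3.0)) == 0.0

    def test_doubling_multiplicity_doubles_value(self, wt_params, rng):
        k = rng.integers(0, 101, size=200)
        one = DisplacementSample(k_values=k, n_trials=100)
        two = DisplacementSample(k_values=np.concatenate([k, k]), n_trials=100)
        assert bb_neg_loglik(two, wt_params) == pytest.approx(
            2 * bb_neg_loglik(one, wt_params), rel=1e-12
        )

    def test_out_of_support_counts_rejected(self):
        with pytest.raises(ValueError):
            DisplacementSample(k_values=[7], n_trials=5)

    def test_mean_approaches_entropy(self, wt_params):
        # per-observation mean NLL at the true parameters estimates the
        # entropy of the displacement law
        n = 100
        s = _sample(wt_params, n, 20_000, seed=8)
        pmf = np.asarray(bb_pmf(np.arange(n + 1), n, wt_params))
        logp = np.asarray(bb_log_pmf(np.arange(n + 1), n, wt_params))
        entropy = float(-(pmf * logp).sum())
        sd = float(np.sqrt((pmf * logp**2).sum() - entropy**2))
        mean_nll = bb_neg_loglik(s, wt_params) / len(s)
        assert abs(mean_nll - entropy) < 4 * sd / np.sqrt(len(s))


class TestMomInit:
    def test_symmetric_sample_gives_equal_shapes(self):
        k = np.array([1, 2, 3, 4, 5, 6, 7, 2, 3, 4, 5, 6, 1, 7, 4])
        s = DisplacementSample(k_values=k, n_trials=8)  # mean n/2
        a0, b0 = mom_init(s)
        assert a0 == pytest.approx(b0, rel=1e-9)

    def test_constant_sample_falls_back_with_warning(self):
        s = DisplacementSample(k_values=[3] * 20, n_trials=10)
        with pytest.warns(UserWarning):
            assert mom_init(s) == (1.0, 1.0)

    def test_underdispersed_sample_falls_back(self):
        # spread far below the binomial variance at the sample mean
        k = np.repeat([40, 41], 250)
        s = DisplacementSample(k_values=k, n_trials=100)
        with pytest.warns(UserWarning):
            assert mom_init(s) == (1.0, 1.0)

    def test_recovers_truth_roughly(self, wt_params):
        s = _sample(wt_params, 100, 20_000, seed=3)
        a0, b0 = mom_init(s)
        assert a0 == pytest.approx(wt_params.alpha, rel=0.2)
        assert b0 == pytest.approx(wt_params.beta, rel=0.2)


class TestFitMle:
    def test_parameter_recovery_within_three_se(self, wt_params):
        s = _sample(wt_params, 100, 20_000, seed=17)
        fit = fit_mle(s)
        assert fit.converged
        assert abs(fit.alpha_hat - wt_params.alpha) < 3 * fit.stderr_alpha
        assert abs(fit.beta_hat - wt_params.beta) < 3 * fit.stderr_beta

    def test_recovery_at_uniform_point(self):
        p = ModelParams(1.0, 1.0)
        s = _sample(p, 3, 20_000, seed=5)
        fit = fit_mle(s)
        assert fit.alpha_hat == pytest.approx(1.0, abs=0.1)
        assert fit.beta_hat == pytest.approx(1.0, abs=0.1)

    def test_boundary_sample_raises(self):
        s = DisplacementSample(k_values=[0] * 50, n_trials=10)
        with pytest.raises(ValueError, match="degenerate"):
            fit_mle(s)

    def test_minimum_sample_size_enforced(self):
        s = DisplacementSample(k_values=[1, 2, 3], n_trials=10)
        with pytest.raises(ValueError, match="at least"):
            fit_mle(s)

    def test_ordering_invariance(self, wt_params, rng):
        k = sample_displacement_steps(100, wt_params, 2000, seed=9)
        s1 = DisplacementSample(k_values=k, n_trials=100)
        s2 = DisplacementSample(k_values=rng.permutation(k), n_trials=100)
        f1, f2 = fit_mle(s1), fit_mle(s2)
        assert f1.alpha_hat == pytest.approx(f2.alpha_hat, rel=1e-9)
        assert f1.beta_hat == pytest.approx(f2.beta_hat, rel=1e-9)

    @pytest.mark.parametrize(
        "alpha,beta", [(8.19, 12.95), (3.18, 4.15), (5.12, 12.87)]
    )
    def test_reparameterization_invariance(self, alpha, beta):
        # optimizing in natural (alpha, beta) space must land on the same
        # optimum as the package's log-space route
        p = ModelParams(alpha, beta)
        s = _sample(p, 100, 5000, seed=23)
        fit = fit_mle(s)
        res = minimize(
            lambda ab: bb_neg_loglik(s, ab),
            [fit.alpha_hat * 1.1, fit.beta_hat * 0.9],
            method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-10},
        )
        assert res.x[0] == pytest.approx(fit.alpha_hat, rel=1e-4)
        assert res.x[1] == pytest.approx(fit.beta_hat, rel=1e-4)

    def test_bias_shrinks_with_sample_size(self, wt_params):
        errs_small, errs_large = [], []
        for seed in range(40):
            small = fit_mle(_sample(wt_params, 100, 100, seed=1000 + seed))
            large = fit_mle(_sample(wt_params, 100, 10_000, seed=2000 + seed))
            errs_small.append(abs(small.alpha_hat - wt_params.alpha))
            errs_large.append(abs(large.alpha_hat - wt_params.alpha))
        assert np.median(errs_large) < np.median(errs_small)


class TestFitJoint:
    def test_two_lag_recovery(self, wt_params):
        s1 = _sample(wt_params, 100, 8000, seed=31)
        s2 = _sample(wt_params, 200, 5000, seed=32)
        fit = fit_joint([s1, s2])
        assert fit.converged
        assert abs(fit.alpha_hat - wt_params.alpha) < 3 * fit.stderr_alpha
        assert abs(fit.beta_hat - wt_params.beta) < 3 * fit.stderr_beta

    def test_duplicated_sample_matches_single_fit(self, wt_params):
        s = _sample(wt_params, 100, 2000, seed=33)
        single = fit_mle(s)
        double = fit_joint([s, s])
        assert double.alpha_hat == pytest.approx(single.alpha_hat, rel=1e-6)
        assert double.beta_hat == pytest.approx(single.beta_hat, rel=1e-6)
        assert double.neg_loglik == pytest.approx(2 * single.neg_loglik, rel=1e-9)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            fit_joint([])


class TestGoodnessOfFit:
    def test_tv_distance_of_model_against_itself_is_zero(self, wt_params):
        # a "sample" laid out exactly proportional to the pmf has TV ~ 0
        n = 20
        pmf = np.asarray(bb_pmf(np.arange(n + 1), n, wt_params))
        counts = np.round(pmf * 200_000).astype(int)
        k = np.repeat(np.arange(n + 1), counts)
        s = DisplacementSample(k_values=k, n_trials=n)
        fit = FitResult(
            alpha_hat=wt_params.alpha, beta_hat=wt_params.beta,
            neg_loglik=0.0, converged=True, stderr_alpha=0.0, stderr_beta=0.0,
            n_samples=len(s),
        )
        report = gof_summary(s, fit, n_fitted_params=0)
        assert report.tv_distance < 5e-3

    def test_far_off_model_rejected(self, wt_params):
        s = _sample(ModelParams(50.0, 50.0), 100, 3000, seed=41)
        fit = FitResult(
            alpha_hat=wt_params.alpha, beta_hat=wt_params.beta,
            neg_loglik=0.0, converged=True, stderr_alpha=0.0, stderr_beta=0.0,
            n_samples=len(s),
        )
        report = gof_summary(s, fit, n_fitted_params=0)
        assert report.p_value < 0.01

    def test_unconverged_fit_rejected(self, wt_params):
        s = _sample(wt_params, 100, 100, seed=42)
        fit = FitResult(
            alpha_hat=1.0, beta_hat=1.0, neg_loglik=0.0, converged=False,
            stderr_alpha=0.0, stderr_beta=0.0, n_samples=len(s),
        )
        with pytest.raises(ValueError, match="converged"):
            gof_summary(s, fit)

    def test_p_values_uniform_under_the_model(self, wt_params):
        # chi-square p over replicates drawn from the tested model itself
        # should be ~Uniform(0, 1)
        n, size = 50, 400
        pmf = np.asarray(bb_pmf(np.arange(n + 1), n, wt_params))
        pvals = []
        for seed in range(200):
            k = sample_displacement_steps(n, wt_params, size, seed=3000 + seed)
            observed = np.bincount(k, minlength=n + 1)
            _, _, p = chi_square_binned(observed, pmf * size)
            pvals.append(p)
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_too_small_sample_cannot_be_binned(self, wt_params):
        s = DisplacementSample(k_values=[3, 4], n_trials=100)
        fit = FitResult(
            alpha_hat=wt_params.alpha, beta_hat=wt_params.beta,
            neg_loglik=0.0, converged=True, stderr_alpha=0.0, stderr_beta=0.0,
            n_samples=2,
        )
        with pytest.raises(ValueError, match="too few"):
            gof_summary(s, fit)
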