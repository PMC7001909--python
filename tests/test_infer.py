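import math

import numpy as np
import pytest
from scipy import stats
from scipy.integrate import quad

from crcbp.adenoma_dist import nb_params
from crcbp.infer import (FitParams, ObsData, PriorSpec, adaptive_mcmc,
                         composite_loglik, fisher_ci, grid_search, log_prior,
                         mixture_likelihood, mle_fit, prevalence_only_loglik)
from crcbp.model_core import ModelParams, Observation, bin_from_report, cells_to_mm
from crcbp.pgf_engine import immigration_pgf


def _a_obs_from_nb(theta, n, seed, ages=None):
    rng = np.random.default_rng(seed)
    if ages is None:
        ages = rng.integers(1, 81, size=n).astype(float)
    obs = []
    for t in np.unique(ages):
        n_t = int((ages == t).sum())
        nb = nb_params(theta, float(t))
        A = stats.nbinom.rvs(nb.r, 1 - nb.p, size=n_t, random_state=rng)
        mm = cells_to_mm(A.astype(float))
        rep = np.where(mm >= 0.5, np.round(mm), 0.0)
        for r in rep:
            lo, hi = bin_from_report(float(r))
            obs.append(Observation("A", float(t), lo, hi))
    return obs


class TestFitParams:
    def test_round_trip_transform(self):
        fit = FitParams(mu1=3.1, ratio=0.34, gamma1=0.2, mu2=1e-5,
                        gamma2=0.4, lam=0.4)
        back = fit.with_vector(fit.to_vector())
        for name in ("mu1", "ratio", "gamma1", "mu2", "gamma2", "lam"):
            assert getattr(back, name) == pytest.approx(getattr(fit, name),
                                                        rel=1e-12)

    def test_tied_death_rates(self):
        th = FitParams(mu1=3.1, ratio=3.1 / 9.0, gamma1=0.2, mu2=1e-5,
                       gamma2=0.4).to_model()
        assert th.d2 == pytest.approx(th.d1)
        assert th.b2 == pytest.approx(th.d1 + 0.4)

    def test_invalid_gamma1(self):
        fit = FitParams(mu1=3.1, ratio=10.0, gamma1=5.0, mu2=1e-5, gamma2=0.4)
        with pytest.raises(ValueError):
            fit.to_model()


class TestMixtureLikelihood:
    def test_lambda_zero_reduces_to_base(self, fig2_params):
        obs = Observation("A", 1.0, 0.0, 100.0)
        assert mixture_likelihood(fig2_params, 0.0, obs) == pytest.approx(
            mixture_likelihood(fig2_params, 0.0, obs))

    def test_zero_bin_lambda_one(self, fig2_params):
        obs = Observation("A", 1.0, -1.0, 100.0)
        assert mixture_likelihood(fig2_params, 1.0, obs) == pytest.approx(1.0)

    def test_zero_bin_mixture_value(self, fig2_params):
        # zero-mass bin at t=1: 0.4 + 0.6 * (1-p)^r ~ 0.663
        obs = Observation("A", 1.0, -1.0, 0.5)
        val = mixture_likelihood(fig2_params, 0.4, obs)
        assert val == pytest.approx(0.4 + 0.6 * 0.438, abs=1e-3)


class TestCompositeLoglik:
    def test_empty_set(self, fig2_params):
        assert composite_loglik(fig2_params, ObsData([])) == 0.0

    def test_weight_equals_duplication(self, fig2_params):
        single = [Observation("A", 40.0, 100.0, 1000.0),
                  Observation("A", 40.0, 100.0, 1000.0)]
        weighted = [Observation("A", 40.0, 100.0, 1000.0, weight=2.0)]
        assert composite_loglik(fig2_params, ObsData(single)) == pytest.approx(
            composite_loglik(fig2_params, ObsData(weighted)), rel=1e-12)

    def test_observation_order_invariance(self, fig2_params):
        obs = [Observation("A", 40.0, 100.0, 1000.0),
               Observation("M", 50.0, 409.0, 11045.0),
               Observation("A", 30.0, -1.0, 409.0)]
        a = composite_loglik(fig2_params, ObsData(obs))
        b = composite_loglik(fig2_params, ObsData(obs[::-1]))
        assert a == pytest.approx(b, rel=1e-12)

    def test_grid_maximum_near_generating_gamma1(self, fig2_params):
        obs = ObsData(_a_obs_from_nb(fig2_params, 3000, seed=11))
        base = FitParams.from_model(fig2_params)
        grid = {"gamma1": np.linspace(0.16, 0.24, 9)}
        surf = grid_search(obs, base, grid)
        best = surf.loc[surf.log_likelihood.idxmax(), "gamma1"]
        assert best == pytest.approx(0.2, abs=0.011)


class TestLogPrior:
    def test_closed_form_value(self):
        fit = FitParams(mu1=3100.0, ratio=3100.0 / 9.0, gamma1=0.165,
                        mu2=1e-7, gamma2=1.76)
        expected = (stats.lognorm.logpdf(3100.0, s=1 / 25, scale=3100.0)
                    + stats.lognorm.logpdf(9.0, s=1 / 3, scale=9.0))
        assert log_prior(fit, PriorSpec()) == pytest.approx(expected, rel=1e-12)

    def test_mode_in_log_space(self):
        pri = PriorSpec(use_b1=False)
        vals = [log_prior(FitParams(mu1=3100.0 * math.exp(d), ratio=1.0,
                                    gamma1=0.2, mu2=1e-7, gamma2=0.4), pri)
                for d in (-0.05, 0.0, 0.05)]
        assert vals[1] > vals[0] and vals[1] > vals[2]

    def test_proper_normalization(self):
        val, _ = quad(lambda x: math.exp(
            log_prior(FitParams(mu1=x, ratio=1.0, gamma1=0.2, mu2=1e-7,
                                gamma2=0.4), PriorSpec(use_b1=False))),
            2000, 5000)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_nonpositive_rejected(self):
        fit = FitParams(mu1=3100.0, ratio=1.0, gamma1=0.2, mu2=1e-7, gamma2=0.4)
        assert math.isinf(log_prior(FitParams(**{**fit.__dict__, "mu1": 0.0}),
                                    PriorSpec()))


class TestPrevalenceOnly:
    def test_mu2_zero_consistency(self):
        th = ModelParams(3.1, 9.0, 8.8, 0.0, 9.2, 8.8)
        no_cancer = ObsData([Observation("M", 50.0, -1.0, 409.0, weight=5.0)])
        assert prevalence_only_loglik(th, no_cancer) == 0.0
        with_cancer = ObsData([Observation("M", 50.0, 409.0, 11045.0)])
        assert math.isinf(prevalence_only_loglik(th, with_cancer))

    def test_matches_bernoulli_mle(self, fig2_params):
        t = 55.0
        p_model = 1.0 - math.exp(immigration_pgf(0.0, t, fig2_params))
        rows = [Observation("M", t, 409.0, math.inf, weight=37.0),
                Observation("M", t, -1.0, 409.0, weight=63.0)]
        ll = prevalence_only_loglik(fig2_params, ObsData(rows))
        # Bernoulli log-likelihood at the model's own rate... but the zero bin
        # includes 1..408 cells; prevalence reduction treats it as no-cancer
        expected = 37.0 * math.log(p_model) + 63.0 * math.log(1 - p_model)
        assert ll == pytest.approx(expected, rel=1e-9)


class TestMleFit:
    def test_one_parameter_recovery(self, fig2_params):
        obs = ObsData(_a_obs_from_nb(fig2_params, 4000, seed=17))
        init = FitParams.from_model(fig2_params).__class__(
            mu1=3.1, ratio=3.1 / 9.0, gamma1=0.14, mu2=1e-5, gamma2=0.4)
        best, _ = mle_fit(obs, init, fix=("mu1", "ratio", "mu2", "gamma2"))
        assert best.gamma1 == pytest.approx(0.2, abs=0.01)

    def test_perturbed_inits_converge_together(self, fig2_params):
        obs = ObsData(_a_obs_from_nb(fig2_params, 2000, seed=19))
        fits = []
        for f in (0.5, 2.0):
            init = FitParams(mu1=3.1 * f, ratio=0.344 / f, gamma1=0.2 * f,
                             mu2=1e-5, gamma2=0.4)
            best, _ = mle_fit(obs, init, fix=("mu2", "gamma2"))
            fits.append(best)
        assert fits[0].gamma1 == pytest.approx(fits[1].gamma1, rel=5e-3)
        assert fits[0].mu1 == pytest.approx(fits[1].mu1, rel=5e-2)

    def test_fisher_ci_covers_truth(self, fig2_params):
        obs = ObsData(_a_obs_from_nb(fig2_params, 4000, seed=23))
        init = FitParams(mu1=3.1, ratio=0.344, gamma1=0.2, mu2=1e-5, gamma2=0.4)
        best, _ = mle_fit(obs, init, fix=("mu2", "gamma2"))
        ci = fisher_ci(obs, best, fix=("mu2", "gamma2"))
        lo, hi = ci["gamma1"]
        assert lo < 0.2 < hi


class TestAdaptiveMcmc:
    def test_samples_known_prior_density(self):
        """With no data the chain targets the prior; the adapted sampler
        reproduces the lognormal's quantiles and lands near the 30%
        acceptance target."""
        obs = ObsData([])  # empty set: likelihood == 0 everywhere
        init = FitParams(mu1=3100.0, ratio=3100.0 / 9.0, gamma1=0.2,
                         mu2=1e-5, gamma2=0.4)
        post = adaptive_mcmc(obs, init, n_steps=4000, seed=3,
                             fix=("ratio", "gamma1", "mu2", "gamma2"),
                             priors=PriorSpec(use_b1=False))
        assert 0.15 <= post.acceptance_rate <= 0.45
        mu1 = post.params["mu1"].to_numpy()[post.n_adapt:]
        assert np.median(mu1) == pytest.approx(3100.0, rel=0.01)
        assert np.std(np.log(mu1)) == pytest.approx(1 / 25, rel=0.25)

    def test_posterior_covers_generating_gamma1(self, fig2_params):
        obs = ObsData(_a_obs_from_nb(fig2_params, 1500, seed=29))
        init = FitParams(mu1=3.1, ratio=0.344, gamma1=0.2, mu2=1e-5,
                         gamma2=0.4)
        best, _ = mle_fit(obs, init, fix=("mu2", "gamma2"))
        post = adaptive_mcmc(obs, best, n_steps=1500, seed=5,
                             fix=("mu2", "gamma2"))
        lo, hi = post.credible_interval("gamma1")
        assert lo < 0.2 < hi
        assert 0.1 <= post.acceptance_rate <= 0.5

    def test_two_seeds_agree(self, fig2_params):
        obs = ObsData(_a_obs_from_nb(fig2_params, 800, seed=31))
        init = FitParams(mu1=3.1, ratio=0.344, gamma1=0.2, mu2=1e-5,
                         gamma2=0.4)
        chains = [adaptive_mcmc(obs, init, n_steps=1200, seed=sd,
                                fix=("mu1", "ratio", "mu2", "gamma2"))
                  for sd in (11, 12)]
        x = [c.params["gamma1"].to_numpy()[c.n_adapt:] for c in chains]
        # split-chain potential-scale-reduction on gamma1
        means = np.array([xi.mean() for xi in x])
        varis = np.array([xi.var(ddof=1) for xi in x])
        n = min(len(xi) for xi in x)
        W = varis.mean()
        B = n * means.var(ddof=1)
        rhat = math.sqrt((W * (n - 1) / n + B / n) / W)
        assert rhat < 1.1


class TestGridSearch:
    def test_single_cell_equals_loglik(self, fig2_params):
        obs = ObsData([Observation("A", 40.0, 100.0, 1000.0)])
        base = FitParams.from_model(fig2_params)
        surf = grid_search(obs, base, {"gamma1": [0.2]})
        assert len(surf) == 1
        assert surf.log_likelihood[0] == pytest.approx(
            composite_loglik(base, obs), rel=1e-12)
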