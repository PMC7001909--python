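import numpy as np
import pytest
from scipy import stats

from crcbp.adenoma_dist import adenoma_mean, nb_params
from crcbp.model_core import ModelParams
from crcbp.simulate import (CohortSpec, cohort_to_observations, gillespie_run,
                            gillespie_sample, hybrid_cohort,
                            single_clone_extinct_frequency, synth_registry)


def _jitter_ks(x, y, seed=0):
    """Two-sample KS on integer samples, made valid by uniform jitter."""
    rng = np.random.default_rng(seed)
    return stats.ks_2samp(x + rng.random(len(x)), y + rng.random(len(y)))


class TestGillespie:
    def test_all_zero_rates_stay_empty(self):
        th = ModelParams(0.0, 9.0, 8.8, 1e-5, 9.2, 8.8)
        t, A, M = gillespie_run(th, 10.0, seed=1)
        assert A[-1] == 0 and M[-1] == 0

    def test_event_times_strictly_increase(self, fig2_params):
        t, A, M = gillespie_run(fig2_params, 3.0, seed=2)
        assert np.all(np.diff(t) > 0)

    def test_seeded_reproducibility(self, fig2_params):
        a1 = gillespie_sample(fig2_params, 5.0, 100, seed=42)
        a2 = gillespie_sample(fig2_params, 5.0, 100, seed=42)
        assert np.array_equal(a1[0], a2[0]) and np.array_equal(a1[1], a2[1])

    def test_event_guard(self, fig2_params):
        with pytest.raises(RuntimeError, match="tau-leaping"):
            gillespie_run(fig2_params, 60.0, seed=3, max_events=10**4)

    def test_mean_matches_analytic(self, fig2_params):
        A, _ = gillespie_sample(fig2_params, 10.0, 4000, seed=5)
        m = adenoma_mean(fig2_params, 10.0)
        se = A.std() / np.sqrt(len(A))
        assert abs(A.mean() - m) < 3.5 * se

    def test_nb_distribution_at_mu2_zero(self, fig2_params):
        """Exact simulation at mu2=0 is distributionally indistinguishable
        from the closed-form negative binomial."""
        th = ModelParams(3.1, 9.0, 8.8, 0.0, 9.2, 8.8)
        A, _ = gillespie_sample(th, 8.0, 3000, seed=8)
        nb = nb_params(th, 8.0)
        ref = stats.nbinom.rvs(nb.r, 1 - nb.p, size=3000,
                               random_state=np.random.default_rng(9))
        assert _jitter_ks(A, ref).pvalue > 0.01


class TestHybridCohort:
    def test_lam_one_all_zero(self, fig2_params):
        df = hybrid_cohort(CohortSpec(n_individuals=50, lam=1.0, seed=1))
        assert (df.A == 0).all() and (df.M == 0).all()

    def test_seeded_reproducibility(self, fig2_params):
        d1 = hybrid_cohort(CohortSpec(n_individuals=200, seed=7))
        d2 = hybrid_cohort(CohortSpec(n_individuals=200, seed=7))
        assert d1.equals(d2)

    def test_a_marginal_matches_exact_gillespie(self, fig2_params):
        """Interval-sampled A agrees in distribution with exact simulation."""
        t = 20.0
        df = hybrid_cohort(CohortSpec(n_individuals=2000, lam=0.0,
                                      ages_to_record=(t,), seed=13))
        A_exact, M_exact = gillespie_sample(fig2_params, t, 2000, seed=14)
        assert _jitter_ks(df.A.to_numpy(), A_exact).pvalue > 0.01
        # cancer-presence rates agree too (coarser check: P(M>0) is tiny here)
        p_h = (df.M > 0).mean()
        p_e = (M_exact > 0).mean()
        se = np.sqrt((p_e * (1 - p_e) + p_h * (1 - p_h)) / 2000 + 1e-12)
        assert abs(p_h - p_e) < 4 * se + 1e-3

    def test_a_moments_match_nb(self, fig2_params):
        df = hybrid_cohort(CohortSpec(n_individuals=4000, lam=0.0,
                                      ages_to_record=(40.0,), seed=15))
        nb = nb_params(fig2_params, 40.0, deplete_by_mu2=True)
        mean = nb.r * nb.p / (1 - nb.p)
        var = nb.r * nb.p / (1 - nb.p) ** 2
        se = np.sqrt(var / 4000)
        assert abs(df.A.mean() - mean) < 3.5 * se


class TestSingleCloneOracle:
    def test_extinction_frequency_matches_pgf(self, fig2_params):
        """P(M(t)=0 | one initial A cell) from exact simulation agrees with
        the single-clone PGF at s=0."""
        from crcbp.pgf_engine import single_clone_pgf

        t = 20.0
        freq = single_clone_extinct_frequency(fig2_params, t, 20000, seed=21)
        model = float(np.real(single_clone_pgf(0.0, t, fig2_params)))
        se = np.sqrt(model * (1 - model) / 20000)
        assert abs(freq - model) < 3.5 * se


class TestCohortToObservations:
    def test_row_counts_and_zero_bins(self, fig2_params):
        df = hybrid_cohort(CohortSpec(n_individuals=300, seed=3))
        obs = cohort_to_observations(df)
        assert len(obs) == 2 * len(df)
        zero_a = [o for o in obs if o.compartment == "A" and o.contains_zero]
        assert len(zero_a) >= 0.3 * len(df)  # resistant + small lesions


class TestSynthRegistry:
    def test_no_detection_no_incidence(self, fig2_params):
        spec = CohortSpec(n_individuals=300, seed=5)
        _, registry, tumors, _ = synth_registry(spec, detect_mm=np.inf)
        assert registry.incident_count.sum() == 0
        assert len(tumors) == 0

    def test_at_risk_bookkeeping(self, fig2_params):
        spec = CohortSpec(n_individuals=2000, seed=6)
        _, registry, _, truth = synth_registry(spec, detect_mm=2.0)
        inc = registry.incident_count.to_numpy()
        at_risk = registry.at_risk_count.to_numpy()
        # at-risk declines by exactly the incident count each year
        assert np.array_equal(at_risk[:-1] - inc[1:], at_risk[1:])
        # prevalent = cumulative incidence strictly before each age
        prev = truth["prevalent_true"]
        assert np.array_equal(prev[1:], np.cumsum(inc)[:-1])

    def test_adenoma_table_schema(self, fig2_params):
        spec = CohortSpec(n_individuals=200, seed=7)
        adenoma, _, _, _ = synth_registry(spec)
        assert set(adenoma.columns) == {"age", "size_mm"}
        assert ((adenoma.age >= 40) & (adenoma.age < 50)).all()
        assert (adenoma.size_mm >= 0).all()
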