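import math

import numpy as np
import pytest

from crcbp.cancer_tail import (V_and_derivatives, cancer_bin_likelihood,
                               cancer_cdf, cancer_cdf_approx, cancer_cdf_batch,
                               find_saddle)
from crcbp.model_core import ModelParams, Observation, mm_to_cells
from crcbp.pgf_engine import exact_cdf_small


class TestVAndDerivatives:
    def test_pure_pole_closed_form_saddle(self):
        """With mu1 = 0 (G == 1), V = -log(1-s) - (N+1) log s and the saddle
        sits at (N+1)/(N+2)."""
        th = ModelParams(0.0, 9.0, 8.8, 1e-5, 9.2, 8.8)
        N = 1000
        st = find_saddle(th, 50.0, N)
        assert st.s_star == pytest.approx((N + 1) / (N + 2), rel=1e-8)
        V, V1, V2 = V_and_derivatives(st.s_star, th, 50.0, N)
        assert abs(V1) <= 1e-8 * (N + 1)
        assert V2 > 0

    def test_saddle_residual_small(self, fig2_params):
        st = find_saddle(fig2_params, 50.0, 10**4)
        _, V1, V2 = V_and_derivatives(st.s_star, fig2_params, 50.0, 10**4)
        assert abs(V1) <= 1e-6 * 10**4
        assert V2 > 0

    def test_domain(self, fig2_params):
        with pytest.raises(ValueError):
            V_and_derivatives(1.5, fig2_params, 50.0, 100)

    def test_closed_fd_matches_ode_analytic(self, fig2_params):
        """Finite differences on the hypergeometric log G agree with the
        analytically differentiated Riccati system."""
        for s in (0.3, 0.9, 0.99):
            Vc, V1c, V2c = V_and_derivatives(s, fig2_params, 40.0, 500,
                                             method="closed")
            Vo, V1o, V2o = V_and_derivatives(s, fig2_params, 40.0, 500,
                                             method="ode")
            assert Vc == pytest.approx(Vo, rel=1e-8)
            assert V1c == pytest.approx(V1o, rel=1e-6)
            assert V2c == pytest.approx(V2o, rel=1e-5)


class TestCancerCdfApprox:
    def test_mu2_zero_gives_one(self):
        th = ModelParams(3.1, 9.0, 8.8, 0.0, 9.2, 8.8)
        assert cancer_cdf_approx(th, 50.0, 500) == pytest.approx(1.0)

    def test_quadrature_tracks_exact_within_one_percent(self, fig2_params):
        for t in (35.0, 50.0, 60.0):
            for N in (150, 700, 2000):
                e = exact_cdf_small(fig2_params, t, N)
                q = cancer_cdf_approx(fig2_params, t, N)
                assert q == pytest.approx(e, rel=1e-2)

    def test_gaussian_leading_order_inflates(self):
        """The leading-order Gaussian formula carries the known e/sqrt(2 pi)
        inflation in the pole-dominated regime and is clipped to 1."""
        th = ModelParams(0.0, 9.0, 8.8, 1e-5, 9.2, 8.8)
        st = find_saddle(th, 50.0, 500)
        raw = math.exp(st.V) / math.sqrt(2 * math.pi * st.V2)
        assert raw == pytest.approx(math.e / math.sqrt(2 * math.pi), rel=1e-2)
        assert cancer_cdf_approx(th, 50.0, 500, method="gaussian") == 1.0

    def test_monotone_in_N_and_age(self, fig2_params):
        Ns = np.array([200, 1000, 10**4, 10**6, 10**8])
        vals = cancer_cdf_batch(fig2_params, 60.0, Ns)
        assert np.all(np.diff(vals) >= -1e-9)
        by_age = [cancer_cdf_approx(fig2_params, t, 1000) for t in (40, 50, 60, 70)]
        assert np.all(np.diff(by_age) <= 1e-9)  # older -> stochastically larger

    def test_large_N_limit_is_one(self, fig2_params):
        assert cancer_cdf_approx(fig2_params, 40.0, 10**10) == pytest.approx(1.0, abs=1e-4)


class TestCancerCdf:
    def test_small_N_routes_to_exact(self, fig2_params):
        for N in (0, 10, 60):
            assert cancer_cdf(fig2_params, 50.0, N) == pytest.approx(
                exact_cdf_small(fig2_params, 50.0, N), rel=1e-9)

    def test_negative_N(self, fig2_params):
        assert cancer_cdf(fig2_params, 50.0, -1) == 0.0


class TestCancerBinLikelihood:
    def test_degenerate_bin_rejected(self, fig2_params):
        with pytest.raises(ValueError):
            cancer_bin_likelihood(fig2_params, Observation("M", 50.0, 10.0, 10.0))

    def test_prevalent_case_bin(self, fig2_params):
        obs = Observation("M", 55.0, float(mm_to_cells(39.5)), math.inf)
        val = cancer_bin_likelihood(fig2_params, obs)
        assert 0.0 < val < 1.0

    def test_telescoping_partition(self, fig2_params):
        """Bin likelihoods over a partition of (100, 1e6] telescope to
        CDF(1e6) - CDF(100)."""
        edges = [100, 1000, 10**4, 10**5, 10**6]
        parts = [cancer_bin_likelihood(
            fig2_params, Observation("M", 50.0, float(a), float(b)))
            for a, b in zip(edges[:-1], edges[1:])]
        total = cancer_cdf(fig2_params, 50.0, 10**6) - cancer_cdf(fig2_params, 50.0, 100)
        assert sum(parts) == pytest.approx(total, abs=2e-3)
        assert sum(parts) <= 1.0

    def test_zero_bin_uses_cdf(self, fig2_params):
        obs = Observation("M", 50.0, -1.0, 409.0)
        assert cancer_bin_likelihood(fig2_params, obs) == pytest.approx(
            cancer_cdf(fig2_params, 50.0, 409), rel=1e-9)


class TestJointCoefCdf:
    def test_a0_saddle_matches_exact_nb_form(self, fig2_params):
        """The generic saddle-quadrature coefficient CDF for the
        joint-with-M-extinct PGF agrees with its exact negative-binomial
        representation at large k."""
        import math as _math

        from scipy import stats as _stats

        from crcbp.cancer_tail import coef_cdf
        from crcbp.risk import joint_m0_nb

        log_m0, sc, q = joint_m0_nb(fig2_params, 50.0)
        for k in (5000, 10**5):
            exact = _math.exp(log_m0) * float(_stats.nbinom.cdf(k, sc, 1 - q))
            assert coef_cdf(fig2_params, 50.0, k) == pytest.approx(exact, rel=5e-3)
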