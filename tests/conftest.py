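import numpy as np
import pytest
from scipy.linalg import expm

from crcbp.model_core import ModelParams
from crcbp.simulate import CohortSpec, cohort_to_observations, hybrid_cohort


@pytest.fixture(scope="session")
def fig2_params() -> ModelParams:
    """The biologically motivated simulation parameter set."""
    return ModelParams(mu1=3.1, b1=9.0, d1=8.8, mu2=1e-5, b2=9.2, d2=8.8)


@pytest.fixture(scope="session")
def small_params() -> ModelParams:
    """Rates small enough for a truncated master-equation oracle."""
    return ModelParams(mu1=0.4, b1=0.6, d1=0.5, mu2=0.3, b2=0.7, d2=0.4)


def master_equation_dist(theta: ModelParams, t: float, a_max: int = 40,
                         m_max: int = 40) -> np.ndarray:
    """Joint P(A=i, M=j) at time t by matrix exponential of the truncated
    generator (independent oracle; valid when the truncated mass is tiny)."""
    na, nm = a_max + 1, m_max + 1
    n = na * nm
    Q = np.zeros((n, n))
    mu1, b1, d1, mu2, b2, d2 = theta.as_tuple()

    def idx(a, m):
        return a * nm + m

    for a in range(na):
        for m in range(nm):
            i = idx(a, m)
            if a + 1 < na:
                Q[idx(a + 1, m), i] += mu1 + b1 * a
            if a > 0:
                Q[idx(a - 1, m), i] += d1 * a
                if m + 1 < nm:
                    Q[idx(a - 1, m + 1), i] += mu2 * a
            if m + 1 < nm:
                Q[idx(a, m + 1), i] += b2 * m
            if m > 0:
                Q[idx(a, m - 1), i] += d2 * m
            Q[i, i] -= (mu1 + (b1 + d1 + mu2) * a + (b2 + d2) * m)
    p0 = np.zeros(n)
    p0[idx(0, 0)] = 1.0
    p = expm(Q * t) @ p0
    joint = p.reshape(na, nm)
    assert joint.sum() > 0.999, "master-equation truncation too aggressive"
    return joint


@pytest.fixture(scope="session")
def sim_cohort():
    """Reduced synthetic cohort at the simulation parameters (shared by the
    recovery and conditional-risk checks)."""
    spec = CohortSpec(n_individuals=8000, seed=20260915)
    df = hybrid_cohort(spec)
    return spec, df


@pytest.fixture(scope="session")
def cohort_obs(sim_cohort):
    from crcbp.infer import ObsData

    _, df = sim_cohort
    return ObsData(cohort_to_observations(df))
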