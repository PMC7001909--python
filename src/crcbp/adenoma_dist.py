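"""Closed-form size distribution and binned likelihood for compartment A.

With the malignant transition switched off (mu2 = 0) the adenoma compartment
is a linear birth-death process with immigration and its size at age t is
negative binomial,

    P(A(t) = k) = (1-p)^r C(r+k-1, k) p^k,
    r = mu1/b1,   p(t) = b1 (e^{g1 t} - 1) / (b1 e^{g1 t} - d1),

with g1 = b1 - d1 (and the g1 -> 0 limit p = b1 t / (1 + b1 t)).  Binned
likelihoods are regularized-incomplete-beta tail differences,

    L(theta | (L, U], t) = I_p(L+1, r) - I_p(U+1, r),

where I_p(k, r) = P(A >= k) is the upper-tail of the negative binomial.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import special, stats

from .model_core import ModelParams, Observation

__all__ = ["NBParams", "nb_params", "adenoma_pmf", "adenoma_log_pmf",
           "adenoma_cdf", "adenoma_mean", "adenoma_bin_likelihood",
           "adenoma_bin_logliks",
           "adenoma_bin_likelihoods"]


@dataclass(frozen=True)
class NBParams:
    r: float  # dispersion mu1/b1 (real-valued)
    p: float  # success probability at the given age

    def __post_init__(self) -> None:
        if self.r <= 0:
            raise ValueError("r must be > 0")
        if not (0.0 <= self.p < 1.0):
            raise ValueError("p must be in [0, 1)")


def nb_params(theta: ModelParams, t: float, *, deplete_by_mu2: bool = False) -> NBParams:
    """Negative-binomial parameters of A(t).

    ``deplete_by_mu2`` folds the malignant transition into an effective death
    rate d1 + mu2 for the A marginal of the full model; the default (off)
    matches the mu2 = 0 derivation used throughout the fitting.
    """
    if theta.b1 <= 0:
        raise ValueError("b1 must be > 0 for the negative-binomial solution")
    if t < 0:
        raise ValueError("age must be >= 0")
    b1 = theta.b1
    d1 = theta.d1 + (theta.mu2 if deplete_by_mu2 else 0.0)
    g1 = b1 - d1
    if t == 0:
        return NBParams(r=theta.mu1 / b1, p=0.0)
    if abs(g1) < 1e-12 * b1:
        p = b1 * t / (1.0 + b1 * t)
    else:
        # p = b1(e^{g1 t}-1)/(b1 e^{g1 t}-d1), stably via expm1
        em1 = np.expm1(g1 * t)
        p = b1 * em1 / (b1 * em1 + g1)
    return NBParams(r=theta.mu1 / b1, p=float(p))


def adenoma_mean(theta: ModelParams, t) -> float:
    """E[A(t)] = mu1 (e^{g1 t} - 1) / g1 (limit mu1*t at g1 = 0)."""
    g1 = theta.gamma1
    t = np.asarray(t, dtype=float)
    if abs(g1) < 1e-14:
        out = theta.mu1 * t
    else:
        out = theta.mu1 * np.expm1(g1 * t) / g1
    return float(out) if out.ndim == 0 else out


def adenoma_log_pmf(theta: ModelParams, t: float, k, **kw):
    nb = nb_params(theta, t, **kw)
    k = np.asarray(k)
    if nb.p == 0.0:
        return np.where(k == 0, 0.0, -np.inf)
    return stats.nbinom.logpmf(k, nb.r, 1.0 - nb.p)


def adenoma_pmf(theta: ModelParams, t: float, k, **kw):
    return np.exp(adenoma_log_pmf(theta, t, k, **kw))


def adenoma_cdf(theta: ModelParams, t: float, k, **kw):
    nb = nb_params(theta, t, **kw)
    k = np.asarray(k)
    if nb.p == 0.0:
        return np.where(k >= 0, 1.0, 0.0)
    return stats.nbinom.cdf(k, nb.r, 1.0 - nb.p)


def _upper_tail(k, nb: NBParams):
    """I_p(k, r) = P(A >= k); k may be an array; k <= 0 gives 1."""
    k = np.asarray(k, dtype=float)
    out = np.ones_like(k)
    pos = k > 0
    if np.any(pos):
        # P(NB(r, 1-p) >= k) = betainc(k, r, p)
        out = np.where(pos, special.betainc(np.maximum(k, 1.0), nb.r, nb.p), out)
    return out


def adenoma_bin_likelihood(theta: ModelParams, obs: Observation, **kw) -> float:
    """P(L < A(t) <= U) for one compartment-A observation."""
    if obs.compartment != "A":
        raise ValueError("observation is not a compartment-A finding")
    return float(_bin_prob(theta, obs.age, np.array([obs.lower]), np.array([obs.upper]), **kw)[0])


def adenoma_bin_likelihoods(theta: ModelParams, t: float, lower, upper, **kw):
    """Vectorized P(L < A(t) <= U) over bins at one age."""
    return _bin_prob(theta, t, np.asarray(lower, float), np.asarray(upper, float), **kw)


def _bin_prob(theta, t, lower, upper, **kw):
    if np.any(lower >= upper):
        raise ValueError("need lower < upper for every bin")
    lower = np.floor(lower)  # (L, U] on integer counts
    upper = np.where(np.isinf(upper), upper, np.floor(upper))
    nb = nb_params(theta, t, **kw)
    if nb.p == 0.0:
        return np.where(lower < 0, 1.0, 0.0) * np.ones_like(lower)
    lo = _upper_tail(lower + 1.0, nb)
    hi = np.where(np.isinf(upper), 0.0, _upper_tail(upper + 1.0, nb))
    return np.clip(lo - hi, 0.0, 1.0)


def nb_bin_log_prob(r: float, p: float, lower, upper):
    """log P(L < X <= U) for X ~ NB(r, success probability p), stable far
    into both tails.

    Where the incomplete-beta difference underflows (a bin many orders of
    magnitude away from the bulk), the bin probability is rebuilt in log
    space from the log-pmf with a geometric tail-sum correction; this keeps
    displaced optimizer starts on a finite, sloped surface.
    """
    lower = np.floor(np.asarray(lower, float))
    upper = np.asarray(upper, float)
    upper = np.where(np.isinf(upper), upper, np.floor(upper))
    if np.any(lower >= upper):
        raise ValueError("need lower < upper for every bin")
    if p == 0.0:
        return np.where(lower < 0, 0.0, -np.inf) * np.ones_like(lower)
    nb = NBParams(r=r, p=p)
    lo = _upper_tail(lower + 1.0, nb)
    hi = np.where(np.isinf(upper), 0.0, _upper_tail(upper + 1.0, nb))
    prob = np.clip(lo - hi, 0.0, 1.0)
    out = np.full(prob.shape, -np.inf)
    ok = prob > 1e-280
    out[ok] = np.log(prob[ok])
    if np.all(ok):
        return out
    mean = r * p / (1.0 - p)
    for i in np.nonzero(~ok)[0]:
        L, U = lower[i], upper[i]
        if L + 1 > mean:  # upper tail: sf(k) ~ pmf(k+1)/(1-p)
            lsf_L = float(stats.nbinom.logpmf(L + 1, r, 1.0 - p)) \
                - math.log1p(-p)
            if math.isinf(U):
                out[i] = lsf_L
            else:
                lsf_U = float(stats.nbinom.logpmf(U + 1, r, 1.0 - p)) \
                    - math.log1p(-p)
                with np.errstate(invalid="ignore"):
                    out[i] = lsf_L + math.log1p(
                        -math.exp(min(lsf_U - lsf_L, 0.0)))
        else:  # lower tail: cdf(k) ~ pmf(k)/(1 - pmf(k-1)/pmf(k))
            k = max(U, 0.0)
            rlow = k / ((r + k - 1.0) * p) if k >= 1 else 0.0
            lcdf = float(stats.nbinom.logpmf(k, r, 1.0 - p))
            if 0.0 < rlow < 1.0:
                lcdf -= math.log1p(-rlow)
            out[i] = lcdf
    return out


def adenoma_bin_logliks(theta: ModelParams, t: float, lower, upper, **kw):
    """log P(L < A(t) <= U), stable far into both tails."""
    nb = nb_params(theta, t, **kw)
    return nb_bin_log_prob(nb.r, nb.p, lower, upper)
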