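"""Composite likelihood, priors, MLE, grid search, and adaptive MCMC.

The searched vector is the reparameterization (mu1, mu1/b1, gamma1, mu2,
gamma2) -- immigration rate, dispersion ratio, and the two net growth rates --
plus optionally the resistant fraction lambda.  Death rates are tied,
d2 = d1 (the separate (b2, d2) pair is not identifiable from size data once
gamma2 is fixed), unless an explicit d2 is supplied.

The composite log-likelihood adds the compartment-A binned negative-binomial
terms and the compartment-M binned saddle-point terms, each passed through
the zero-inflation mixture

    L(theta, lam | O) = lam + (1-lam) L(theta | O)   if 0 in the bin,
                        (1-lam) L(theta | O)          otherwise.

Optimization and sampling operate on log-transformed parameters (logit for
lambda).  The adaptive Metropolis chain uses a diagonal proposal whose global
scale follows a Robbins-Monro recursion targeting 30% acceptance and whose
per-coordinate scales track the chain's running spread; adaptation is frozen
after the first half of the chain.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .adenoma_dist import adenoma_bin_likelihoods, adenoma_bin_logliks
from .cancer_tail import cancer_cdf_batch, N_MIN_APPROX
from .model_core import MixtureParam, ModelParams, Observation
from .pgf_engine import exact_cdf_small, immigration_pgf, N_MAX_EXACT

__all__ = ["FitParams", "ObsData", "PriorSpec", "PosteriorSample",
           "mixture_likelihood", "composite_loglik", "log_prior",
           "prevalence_only_loglik", "mle_fit", "fisher_ci",
           "adaptive_mcmc", "grid_search"]

logger = logging.getLogger(__name__)

_POSITIVE = ("mu1", "ratio", "gamma1", "mu2", "gamma2")


@dataclass(frozen=True)
class FitParams:
    """Search-space parameter vector (see module docstring)."""

    mu1: float
    ratio: float      # mu1 / b1
    gamma1: float
    mu2: float
    gamma2: float
    lam: float | None = None
    d2_fixed: float | None = None  # default: d2 = d1 (tied death rates)

    def to_model(self) -> ModelParams:
        b1 = self.mu1 / self.ratio
        d1 = b1 - self.gamma1
        if d1 < 0:
            raise ValueError("gamma1 > b1 implies a negative death rate")
        d2 = d1 if self.d2_fixed is None else self.d2_fixed
        b2 = d2 + self.gamma2
        if b2 < 0:
            raise ValueError("negative b2")
        return ModelParams(mu1=self.mu1, b1=b1, d1=d1, mu2=self.mu2,
                           b2=b2, d2=d2)

    @classmethod
    def from_model(cls, theta: ModelParams, lam: float | None = None):
        return cls(mu1=theta.mu1, ratio=theta.mu1 / theta.b1,
                   gamma1=theta.gamma1, mu2=theta.mu2, gamma2=theta.gamma2,
                   lam=lam)

    # -- transformed-space round trip ------------------------------------
    def free_names(self, fix: tuple = ()) -> list[str]:
        names = [n for n in _POSITIVE if n not in fix]
        if self.lam is not None and "lam" not in fix:
            names.append("lam")
        return names

    def to_vector(self, fix: tuple = ()) -> np.ndarray:
        out = []
        for n in self.free_names(fix):
            v = getattr(self, n)
            out.append(math.log(v) if n != "lam"
                       else math.log(v / (1.0 - v)))
        return np.array(out)

    def with_vector(self, x: np.ndarray, fix: tuple = ()) -> "FitParams":
        upd = {}
        for n, xi in zip(self.free_names(fix), x):
            xi = min(max(xi, -700.0), 700.0)
            upd[n] = math.exp(xi) if n != "lam" else 1.0 / (1.0 + math.exp(-xi))
        return replace(self, **upd)


class ObsData:
    """Observations aggregated by compartment, age, and bin (weights summed)."""

    def __init__(self, observations: list[Observation]):
        agg: dict[tuple, float] = {}
        for o in observations:
            key = (o.compartment, o.age, o.lower, o.upper)
            agg[key] = agg.get(key, 0.0) + o.weight
        self.groups: dict[str, dict[float, tuple]] = {"A": {}, "M": {}}
        by_age: dict[tuple, list] = {}
        for (comp, age, lo, hi), w in agg.items():
            by_age.setdefault((comp, age), []).append((lo, hi, w))
        for (comp, age), rows in by_age.items():
            rows.sort()
            lo = np.array([r[0] for r in rows])
            hi = np.array([r[1] for r in rows])
            w = np.array([r[2] for r in rows])
            self.groups[comp][age] = (lo, hi, w)
        self.n_rows = {c: sum(len(v[0]) for v in g.values())
                       for c, g in self.groups.items()}
        self.total_weight = {c: sum(float(v[2].sum()) for v in g.values())
                             for c, g in self.groups.items()}

    def __len__(self) -> int:
        return self.n_rows["A"] + self.n_rows["M"]


def mixture_likelihood(theta: ModelParams, lam: float, obs: Observation,
                       **kw) -> float:
    """Eq-12-style zero-inflated single-observation likelihood."""
    from .adenoma_dist import adenoma_bin_likelihood
    from .cancer_tail import cancer_bin_likelihood
    base = adenoma_bin_likelihood(theta, obs) if obs.compartment == "A" \
        else cancer_bin_likelihood(theta, obs, **kw)
    if obs.contains_zero:
        return lam + (1.0 - lam) * base
    return (1.0 - lam) * base


def _m_bin_probs(theta: ModelParams, t: float, lo: np.ndarray, hi: np.ndarray,
                 fast: bool) -> np.ndarray:
    """P(L < M(t) <= U) for all bins at one age via shared CDF evaluations."""
    bounds = np.unique(np.concatenate([
        lo[lo >= 0], hi[np.isfinite(hi)]]).astype(np.int64))
    cdf: dict[int, float] = {}
    small = bounds[bounds < N_MIN_APPROX]
    for b in small:
        cdf[int(b)] = exact_cdf_small(theta, t, int(b)) if b <= N_MAX_EXACT \
            else 1.0
    big = bounds[bounds >= N_MIN_APPROX]
    if len(big):
        kw = dict(n_theta=320, width_sigmas=40.0) if fast else {}
        vals = cancer_cdf_batch(theta, t, big, **kw)
        # enforce CDF monotonicity across the quadrature's small residual noise
        vals = np.maximum.accumulate(vals)
        for b, v in zip(big, vals):
            cdf[int(b)] = float(v)
    hi_v = np.array([cdf[int(h)] if np.isfinite(h) else 1.0 for h in hi])
    lo_v = np.array([cdf[int(l)] if l >= 0 else 0.0 for l in lo])
    return np.clip(hi_v - lo_v, 0.0, 1.0)


def composite_loglik(fit: FitParams | ModelParams, obs: ObsData,
                     lam: float | None = None, fast: bool = True) -> float:
    """Weighted composite log-likelihood over both compartments."""
    if isinstance(fit, FitParams):
        try:
            theta = fit.to_model()
        except ValueError:
            return -math.inf
        lam = fit.lam if lam is None else lam
    else:
        theta = fit
    lam = 0.0 if lam is None else lam
    total = 0.0
    for comp in ("A", "M"):
        for t, (lo, hi, w) in obs.groups[comp].items():
            zero = lo < 0
            if comp == "A":
                logp = adenoma_bin_logliks(theta, t, lo, hi)
                if lam > 0:
                    p = np.exp(logp)
                    logp = np.where(
                        zero, np.log(lam + (1.0 - lam) * p),
                        math.log1p(-lam) + logp)
            else:
                # floor keeps displaced parameter values on a finite surface
                p = np.maximum(_m_bin_probs(theta, t, lo, hi, fast), 1e-220)
                p = np.where(zero, lam + (1.0 - lam) * p, (1.0 - lam) * p)
                logp = np.log(p)
            if np.any(np.isneginf(logp) & (w > 0)):
                bad = np.nonzero(np.isneginf(logp) & (w > 0))[0][0]
                logger.debug("zero likelihood: comp=%s t=%s bin=(%s,%s]",
                             comp, t, lo[bad], hi[bad])
                return -math.inf
            total += float(np.sum(w * logp))
    return total


@dataclass(frozen=True)
class PriorSpec:
    """Lognormal priors on mu1 and b1 ('mean' read as the median; the quoted
    standard deviations 1/25 and 1/3 as the sd of the natural log)."""

    use_mu1: bool = True
    mu1_median: float = 3100.0
    mu1_sdlog: float = 1.0 / 25.0
    use_b1: bool = True
    b1_median: float = 9.0
    b1_sdlog: float = 1.0 / 3.0


def _lognorm_logpdf(x: float, median: float, sdlog: float) -> float:
    if x <= 0:
        return -math.inf
    z = (math.log(x) - math.log(median)) / sdlog
    return -math.log(x * sdlog) - 0.5 * math.log(2 * math.pi) - 0.5 * z * z


def log_prior(fit: FitParams, priors: PriorSpec | None) -> float:
    """Sum of the configured lognormal log-densities (flat elsewhere)."""
    if priors is None:
        return 0.0
    out = 0.0
    if priors.use_mu1:
        out += _lognorm_logpdf(fit.mu1, priors.mu1_median, priors.mu1_sdlog)
    if priors.use_b1:
        out += _lognorm_logpdf(fit.mu1 / fit.ratio, priors.b1_median,
                               priors.b1_sdlog)
    return out


def prevalence_only_loglik(fit: FitParams | ModelParams, obs: ObsData,
                           lam: float | None = None) -> float:
    """Bernoulli cancer-yes/no likelihood: P(M(t) > 0) = (1-lam)(1 - G(0,t)).

    Compartment-M rows with a zero-containing bin count as cancer-free; all
    other M rows count as observed cancers.  Size information is discarded.
    """
    if isinstance(fit, FitParams):
        try:
            theta = fit.to_model()
        except ValueError:
            return -math.inf
        lam = fit.lam if lam is None else lam
    else:
        theta = fit
    lam = 0.0 if lam is None else lam
    total = 0.0
    for t, (lo, hi, w) in obs.groups["M"].items():
        g0 = math.exp(immigration_pgf(0.0, t, theta))
        p_cancer = (1.0 - lam) * (1.0 - g0)
        zero = lo < 0
        p = np.where(zero, 1.0 - p_cancer, p_cancer)
        if np.any((p <= 0) & (w > 0)):
            return -math.inf
        total += float(np.sum(w * np.log(p)))
    return total


# ---------------------------------------------------------------------------
# fitting


def _objective(obs, init, fix, priors, loglik, fast):
    fn = composite_loglik if loglik == "composite" else prevalence_only_loglik

    def neg_logpost(x):
        fit = init.with_vector(x, fix)
        lp = log_prior(fit, priors)
        if not math.isfinite(lp):
            return 1e30
        if loglik == "composite":
            ll = fn(fit, obs, fast=fast)
        else:
            ll = fn(fit, obs)
        if not math.isfinite(ll):
            return 1e30
        return -(ll + lp)

    return neg_logpost


def mle_fit(obs: ObsData, init: FitParams, fix: tuple = (),
            priors: PriorSpec | None = None, loglik: str = "composite",
            maxiter: int = 600, fast: bool = True):
    """Nelder-Mead maximization of the (penalized) composite log-likelihood
    in the log-transformed space.  Returns (FitParams, OptimizeResult)."""
    neg = _objective(obs, init, fix, priors, loglik, fast)
    x0 = init.to_vector(fix)
    res = minimize(neg, x0, method="Nelder-Mead",
                   options={"maxiter": maxiter, "xatol": 1e-5,
                            "fatol": 1e-7, "adaptive": True})
    if not res.success:
        logger.warning("Nelder-Mead did not report convergence: %s",
                       res.message)
    return init.with_vector(res.x, fix), res


def fisher_ci(obs: ObsData, fit: FitParams, fix: tuple = (),
              level: float = 0.95, loglik: str = "composite",
              fast: bool = True, step: float = 1e-3) -> dict:
    """Wald intervals from the observed information (numerical Hessian of the
    log-likelihood in log-parameter space, delta method back to each rate)."""
    from scipy.stats import norm

    neg = _objective(obs, fit, fix, None, loglik, fast)
    x0 = fit.to_vector(fix)
    d = len(x0)
    H = np.empty((d, d))
    f0 = neg(x0)
    for i in range(d):
        for j in range(i, d):
            ei = np.zeros(d); ei[i] = step
            ej = np.zeros(d); ej[j] = step
            if i == j:
                H[i, i] = (neg(x0 + ei) - 2 * f0 + neg(x0 - ei)) / step**2
            else:
                H[i, j] = H[j, i] = (
                    neg(x0 + ei + ej) - neg(x0 + ei - ej)
                    - neg(x0 - ei + ej) + neg(x0 - ei - ej)) / (4 * step**2)
    cov = np.linalg.inv(H)
    z = norm.ppf(0.5 + level / 2.0)
    out = {}
    for i, name in enumerate(fit.free_names(fix)):
        se = math.sqrt(max(cov[i, i], 0.0))
        lo, hi = x0[i] - z * se, x0[i] + z * se
        if name == "lam":
            f = lambda v: 1.0 / (1.0 + math.exp(-v))
        else:
            f = math.exp
        out[name] = (f(lo), f(hi))
    return out


@dataclass
class PosteriorSample:
    names: list[str]
    params: pd.DataFrame        # natural-scale chain, one column per name
    log_likelihood: np.ndarray
    log_prior: np.ndarray
    accepted: np.ndarray
    n_adapt: int                # adaptation frozen after this many steps
    step_scale_trace: np.ndarray

    @property
    def acceptance_rate(self) -> float:
        return float(np.mean(self.accepted[self.n_adapt:]))

    def posterior(self) -> np.ndarray:
        return self.log_likelihood + self.log_prior

    def mode(self) -> dict:
        post = self.posterior()[self.n_adapt:]
        idx = self.n_adapt + int(np.argmax(post))
        return self.params.iloc[idx].to_dict()

    def credible_interval(self, name: str, level: float = 0.95):
        tail = (1.0 - level) / 2.0
        x = self.params[name].to_numpy()[self.n_adapt:]
        return float(np.quantile(x, tail)), float(np.quantile(x, 1.0 - tail))


def adaptive_mcmc(obs: ObsData, init: FitParams, n_steps: int, seed: int,
                  fix: tuple = (), priors: PriorSpec | None = None,
                  target_accept: float = 0.3, loglik: str = "composite",
                  fast: bool = True) -> PosteriorSample:
    """Adaptive random-walk Metropolis chain (see module docstring)."""
    rng = np.random.default_rng(seed)
    neg = _objective(obs, init, fix, priors, loglik, fast)
    names = init.free_names(fix)
    d = len(names)
    x = init.to_vector(fix)
    f = -neg(x)
    if not math.isfinite(f) or f <= -1e29:
        raise ValueError("initial point has non-finite posterior")
    n_adapt = n_steps // 2
    log_s = math.log(0.1)
    scales = np.ones(d)
    chain = np.empty((n_steps, d))
    ll = np.empty(n_steps)
    lp = np.empty(n_steps)
    acc = np.zeros(n_steps, dtype=bool)
    strace = np.empty(n_steps)
    n_acc_recent = 0
    for i in range(n_steps):
        prop = x + math.exp(log_s) * scales * rng.standard_normal(d)
        fp = -neg(prop)
        if math.log(rng.random()) < fp - f:
            x, f = prop, fp
            acc[i] = True
        if i < n_adapt:
            log_s += (float(acc[i]) - target_accept) / (1.0 + i) ** 0.6
            if i >= 200 and i % 100 == 0:
                recent = chain[i // 2:i]
                sd = recent.std(axis=0)
                if np.all(sd > 0):
                    sd = sd / math.exp(np.mean(np.log(sd)))
                    scales = 0.5 * scales + 0.5 * sd
        chain[i] = x
        strace[i] = math.exp(log_s)
        fit_i = init.with_vector(x, fix)
        lp[i] = log_prior(fit_i, priors)
        ll[i] = f - lp[i]
    if not acc[n_adapt:].any():
        raise RuntimeError(
            f"no proposals accepted after adaptation; step-size trace tail: "
            f"{strace[-5:]}")
    nat = np.empty_like(chain)
    for j, nm in enumerate(names):
        nat[:, j] = 1.0 / (1.0 + np.exp(-chain[:, j])) if nm == "lam" \
            else np.exp(chain[:, j])
    return PosteriorSample(names=names,
                           params=pd.DataFrame(nat, columns=names),
                           log_likelihood=ll, log_prior=lp, accepted=acc,
                           n_adapt=n_adapt, step_scale_trace=strace)


def grid_search(obs: ObsData, base: FitParams, grid: dict,
                loglik: str = "composite", fast: bool = True) -> pd.DataFrame:
    """Log-likelihood over the cartesian product of the supplied axes."""
    fn = composite_loglik if loglik == "composite" else prevalence_only_loglik
    names = list(grid)
    rows = []
    for combo in itertools.product(*(grid[n] for n in names)):
        fit = replace(base, **dict(zip(names, combo)))
        if loglik == "composite":
            llv = fn(fit, obs, fast=fast)
        else:
            llv = fn(fit, obs)
        rows.append(dict(zip(names, combo), log_likelihood=llv))
    return pd.DataFrame(rows)
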