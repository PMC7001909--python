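"""Probability generating function of the two-type process with immigration.

Let psi(x, s, u) = E[x^{A(u)} s^{M(u)} | A(0)=1, M(0)=0] be the joint PGF of a
single adenoma clone.  Conditioning on the ancestor's first event gives the
backward Kolmogorov (Riccati) equation

    d psi / du = b1 psi^2 - (b1+d1+mu2) psi + d1 + mu2 h(s, u),   psi(., 0) = x,

where h(s, u) is the PGF of a linear birth-death clone started from one M
cell.  Immigration at rate mu1 turns clone arrivals into a Poisson process, so
the population PGF is

    log Phi(x, s, t) = mu1 * Integral_0^t (psi(x, s, u) - 1) du,

and the cancer-compartment PGF is G(s, t) = Phi(1, s, t).

Two evaluation routes are provided and cross-validated:

* **closed** -- substituting z = z0 e^{-g2 u}, z0 = (d2 - b2 s)/(b2 (1 - s)),
  the Riccati linearizes to a Gauss hypergeometric equation.  With
  w_i(z) = z^{rho_i} 2F1(alpha_i, beta_i; c_i; z) the clone PGF is
  psi = (g2/b1) z w'/w and the u-integral telescopes,

      log Phi = mu1 [ (1/b1) log( w(z0) / w(z_t) ) - t ],

  which collapses to log Phi = pref + (mu1/b1) [log K(s) - log(C(s) + D(s) x)]
  with K, C, D built from six 2F1 values (the x-dependence is exactly a
  Moebius factor because x only enters the initial condition).
* **ode** -- direct numerical integration of the Riccati system plus the
  running integral; branch-free (it never takes a complex logarithm) and used
  as the oracle and as the automatic fallback whenever the hypergeometric
  parameterization degenerates (g2 ~ 0, b2 = 0, complex or near-integer
  indicial exponents).

Exact small-N cumulative probabilities are Cauchy-coefficient extractions of
G(s,t)/(1-s) by FFT on a circle |s| = rho < 1.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.special import hyp2f1

from .model_core import ModelParams

__all__ = [
    "PgfValue",
    "single_clone_pgf",
    "immigration_pgf",
    "log_joint_pgf",
    "log_pgf_path",
    "log_pgf_and_derivs_ode",
    "exact_cdf_small",
    "mean_M",
    "N_MAX_EXACT",
]

logger = logging.getLogger(__name__)

#: largest N for which the exact contour-coefficient CDF is attempted
N_MAX_EXACT = 2000


@dataclass(frozen=True)
class PgfValue:
    s: float
    t: float
    value: float
    log_value: float


def mean_M(theta: ModelParams, t) -> float:
    """E[M(t)] = mu1 mu2 [ (e^{g2 t}-1)/g2 - (e^{g1 t}-1)/g1 ] / (g2 - g1),
    with g1 the mu2-depleted adenoma net growth rate b1 - d1 - mu2."""
    g1, g2 = theta.gamma1 - theta.mu2, theta.gamma2
    t = np.asarray(t, dtype=float)

    def _f(g):  # (e^{g t} - 1)/g with g -> 0 limit
        return np.where(abs(g) < 1e-14, t, np.expm1(g * t) / (g if g != 0 else 1.0))

    if abs(g2 - g1) < 1e-12 * max(abs(g1), abs(g2), 1.0):
        # limit: d/dg [(e^{gt}-1)/g]
        g = g1
        out = theta.mu1 * theta.mu2 * (t * np.exp(g * t) / g - np.expm1(g * t) / g**2)
    else:
        out = theta.mu1 * theta.mu2 * (_f(g2) - _f(g1)) / (g2 - g1)
    return float(out) if out.ndim == 0 else out


def bd_clone_pgf(s, u, b: float, d: float):
    """PGF h(s, u) of a single-cell linear birth-death clone (rates b, d)."""
    s = np.asarray(s)
    g = b - d
    if abs(g) > 1e-12 * max(b, d, 1.0):
        E = math.exp(-g * u)
        num = d * (1 - s) - (d - b * s) * E
        den = b * (1 - s) - (d - b * s) * E
    else:  # critical case b = d
        num = d * u * (1 - s) + s  # h = (b u (1-s) + s(1 - ...)) standard limit
        den = b * u * (1 - s) + 1.0
        num = (b * u - (b * u - 1) * s)  # rewrite: h = (bu - (bu-1)s)/(1+bu - bu s)
        den = (1 + b * u - b * u * s)
    return num / den


# ---------------------------------------------------------------------------
# closed (hypergeometric) route


class _HypParams:
    """Per-theta constants of the hypergeometric representation."""

    __slots__ = ("ok", "reason", "g2", "rho1", "rho2", "a1", "b1_", "c1",
                 "a2", "b2_", "c2", "theta")

    def __init__(self, theta: ModelParams):
        self.theta = theta
        mu1, b1, d1, mu2, b2, d2 = theta.as_tuple()
        g2 = b2 - d2
        self.g2 = g2
        self.ok = True
        self.reason = ""
        if b2 <= 0 or abs(g2) < 1e-9 * max(b2, d2, 1.0):
            self.ok, self.reason = False, "g2 ~ 0 or b2 = 0"
            return
        a = b1 + d1 + mu2
        A = a / g2
        disc = A * A - 4.0 * b1 * (d1 + mu2 * d2 / b2) / g2**2
        if disc <= 0:
            self.ok, self.reason = False, "complex indicial exponents"
            return
        sq = math.sqrt(disc)
        self.rho1, self.rho2 = (A + sq) / 2.0, (A - sq) / 2.0
        delta = sq  # rho1 - rho2
        if abs(delta - round(delta)) < 1e-6 or delta < 1e-6:
            self.ok, self.reason = False, "degenerate 2F1 parameters"
            return
        Q1 = -b1 * mu2 / (b2 * g2)
        for i, rho in ((1, self.rho1), (2, self.rho2)):
            c = 2.0 * rho + 1.0 - A
            rad = (c - 1.0) ** 2 + 4.0 * Q1
            if rad < 0:
                self.ok, self.reason = False, "complex 2F1 parameters"
                return
            sr = math.sqrt(rad)
            al, be = ((c - 1.0) + sr) / 2.0, ((c - 1.0) - sr) / 2.0
            if i == 1:
                self.a1, self.b1_, self.c1 = al, be, c
            else:
                self.a2, self.b2_, self.c2 = al, be, c
        # 2F1(a,b;c;z) poles at c = 0, -1, -2, ...
        for c in (self.c1, self.c2):
            if c < 0.5 and abs(c - round(c)) < 1e-6:
                self.ok, self.reason = False, "c at a nonpositive integer"
                return


_HYP_CACHE: dict[tuple, _HypParams] = {}


def _hyp_params(theta: ModelParams) -> _HypParams:
    key = theta.as_tuple()
    hp = _HYP_CACHE.get(key)
    if hp is None:
        hp = _HypParams(theta)
        if len(_HYP_CACHE) > 256:
            _HYP_CACHE.clear()
        _HYP_CACHE[key] = hp
    return hp


def _z0_of_s(theta: ModelParams, s):
    b2, d2 = theta.b2, theta.d2
    return (d2 - b2 * s) / (b2 * (1.0 - s))


def _kcd(theta: ModelParams, t: float, s):
    """K(s), C(s), D(s) and the prefactor of the Moebius form of log Phi.

    log Phi(x, s, t) = pref + (mu1/b1) * (log K - log(C + D x)),
    pref = mu1 t (rho1 g2 / b1 - 1).
    """
    hp = _hyp_params(theta)
    if not hp.ok:
        raise _ClosedFormUnavailable(hp.reason)
    g2 = hp.g2
    b1 = theta.b1
    z0 = _z0_of_s(theta, np.asarray(s))
    zt = z0 * math.exp(-g2 * t)
    F1z0 = hyp2f1(hp.a1, hp.b1_, hp.c1, z0)
    F2z0 = hyp2f1(hp.a2, hp.b2_, hp.c2, z0)
    F1p = hp.a1 * hp.b1_ / hp.c1 * hyp2f1(hp.a1 + 1, hp.b1_ + 1, hp.c1 + 1, z0)
    F2p = hp.a2 * hp.b2_ / hp.c2 * hyp2f1(hp.a2 + 1, hp.b2_ + 1, hp.c2 + 1, z0)
    F1zt = hyp2f1(hp.a1, hp.b1_, hp.c1, zt)
    F2zt = hyp2f1(hp.a2, hp.b2_, hp.c2, zt)
    P1 = (g2 / b1) * (hp.rho1 * F1z0 + z0 * F1p)
    P2 = (g2 / b1) * (hp.rho2 * F2z0 + z0 * F2p)
    E = math.exp(-g2 * t * (hp.rho2 - hp.rho1))
    K = F1z0 * P2 - F2z0 * P1
    C = F1zt * P2 - E * F2zt * P1
    D = -F1zt * F2z0 + E * F2zt * F1z0
    pref = theta.mu1 * t * (hp.rho1 * g2 / b1 - 1.0)
    return K, C, D, pref


class _ClosedFormUnavailable(RuntimeError):
    pass


def _log_phi_closed(x, s, t: float, theta: ModelParams):
    K, C, D, pref = _kcd(theta, t, s)
    with np.errstate(all="ignore"):  # non-finite values trigger ODE fallback
        ratio = K / (C + D * np.asarray(x))
        return pref + theta.mu1 / theta.b1 * np.log(ratio)


# ---------------------------------------------------------------------------
# ODE route (oracle / fallback)


def _ode_psi_logphi(x, s, t: float, theta: ModelParams, rtol: float = 1e-10):
    """Solve the Riccati + running integral for an array of s (scalar x).

    Returns (psi(t), logPhi(t)) arrays, complex when inputs are complex.
    The integral route never takes a complex log, so the returned logPhi is
    on the analytic branch by construction.
    """
    mu1, b1, d1, mu2, b2, d2 = theta.as_tuple()
    s = np.atleast_1d(np.asarray(s))
    n = s.size
    a = b1 + d1 + mu2
    cplx = np.iscomplexobj(s) or np.iscomplexobj(x)
    dtype = complex if cplx else float
    y0 = np.concatenate([np.full(n, x, dtype=dtype), np.zeros(n, dtype=dtype)])

    def rhs(u, y):
        psi = y[:n]
        hval = bd_clone_pgf(s, u, b2, d2) if mu2 > 0 else 0.0
        dpsi = b1 * psi * psi - a * psi + d1 + mu2 * hval
        return np.concatenate([dpsi, mu1 * (psi - 1.0)])

    if t == 0:
        return y0[:n], y0[n:]
    sol = solve_ivp(rhs, (0.0, t), y0, method="RK45", rtol=rtol, atol=1e-13)
    if not sol.success:  # pragma: no cover - diagnostics path
        raise RuntimeError(f"PGF ODE integration failed: {sol.message}")
    return sol.y[:n, -1], sol.y[n:, -1]


def log_pgf_and_derivs_ode(s: float, t: float, theta: ModelParams,
                           rtol: float = 1e-11):
    """(log G, d log G/ds, d^2 log G/ds^2) by analytic differentiation of the
    Riccati system (the quadrature representation of the immigration PGF)."""
    mu1, b1, d1, mu2, b2, d2 = theta.as_tuple()
    a = b1 + d1 + mu2
    g2 = b2 - d2

    def rhs(u, y):
        psi, ps, pss = y[0], y[1], y[2]
        E = math.exp(-g2 * u) if abs(g2) > 0 else 1.0
        num = d2 * (1 - s) - (d2 - b2 * s) * E
        den = b2 * (1 - s) - (d2 - b2 * s) * E
        h = num / den
        n_s = -d2 + b2 * E
        d_s = -b2 + b2 * E
        h_s = (n_s * den - num * d_s) / den**2
        h_ss = -2.0 * d_s * h_s / den
        return [
            b1 * psi * psi - a * psi + d1 + mu2 * h,
            (2 * b1 * psi - a) * ps + mu2 * h_s,
            2 * b1 * (ps * ps + psi * pss) - a * pss + mu2 * h_ss,
            mu1 * (psi - 1.0),
            mu1 * ps,
            mu1 * pss,
        ]

    if t == 0:
        return 0.0, 0.0, 0.0
    sol = solve_ivp(rhs, (0.0, t), [1.0, 0.0, 0.0, 0.0, 0.0, 0.0],
                    method="RK45", rtol=rtol, atol=1e-14)
    if not sol.success:  # pragma: no cover
        raise RuntimeError(f"PGF ODE integration failed: {sol.message}")
    return float(sol.y[3, -1]), float(sol.y[4, -1]), float(sol.y[5, -1])


# ---------------------------------------------------------------------------
# public surface


def single_clone_pgf(s, u: float, theta: ModelParams, x=1.0,
                     method: str = "auto"):
    """psi(x, s, u): joint PGF of one adenoma clone of age u.

    With the default x = 1 this is the M-marginal clone PGF; u = 0 returns x.
    """
    if u < 0:
        raise ValueError("clone age must be >= 0")
    if u == 0:
        return x * np.ones_like(np.asarray(s, dtype=float))
    if theta.mu2 == 0 and np.all(np.asarray(x) == 1.0):
        return np.ones_like(np.asarray(s, dtype=float))
    if method in ("auto", "closed") and _hyp_params(theta).ok:
        hp = _hyp_params(theta)
        g2, b1 = hp.g2, theta.b1
        z0 = _z0_of_s(theta, np.asarray(s))
        zu = z0 * math.exp(-g2 * u)
        F1z0 = hyp2f1(hp.a1, hp.b1_, hp.c1, z0)
        F2z0 = hyp2f1(hp.a2, hp.b2_, hp.c2, z0)
        F1p0 = hp.a1 * hp.b1_ / hp.c1 * hyp2f1(hp.a1 + 1, hp.b1_ + 1, hp.c1 + 1, z0)
        F2p0 = hp.a2 * hp.b2_ / hp.c2 * hyp2f1(hp.a2 + 1, hp.b2_ + 1, hp.c2 + 1, z0)
        G1 = (g2 / b1) * (hp.rho1 * F1z0 + z0 * F1p0) - x * F1z0
        G2 = (g2 / b1) * (hp.rho2 * F2z0 + z0 * F2p0) - x * F2z0
        ktil = -G1 / G2
        Eu = math.exp(-g2 * u * (hp.rho2 - hp.rho1))
        F1 = hyp2f1(hp.a1, hp.b1_, hp.c1, zu)
        F2 = hyp2f1(hp.a2, hp.b2_, hp.c2, zu)
        F1p = hp.a1 * hp.b1_ / hp.c1 * hyp2f1(hp.a1 + 1, hp.b1_ + 1, hp.c1 + 1, zu)
        F2p = hp.a2 * hp.b2_ / hp.c2 * hyp2f1(hp.a2 + 1, hp.b2_ + 1, hp.c2 + 1, zu)
        num = (hp.rho1 * F1 + zu * F1p) + ktil * Eu * (hp.rho2 * F2 + zu * F2p)
        den = F1 + ktil * Eu * F2
        return (g2 / b1) * num / den
    if method == "closed":
        raise _ClosedFormUnavailable(_hyp_params(theta).reason)
    psi, _ = _ode_psi_logphi(x, s, u, theta)
    out = psi if np.iscomplexobj(np.asarray(s)) else psi.real
    return out if np.asarray(s).ndim else out[0]


def log_joint_pgf(x, s, t: float, theta: ModelParams, method: str = "auto"):
    """log Phi(x, s, t) = log E[x^{A(t)} s^{M(t)}] (real s, x in [0, 1])."""
    if t < 0:
        raise ValueError("age must be >= 0")
    if t == 0 or theta.mu1 == 0:
        return np.zeros(np.broadcast(np.asarray(x), np.asarray(s)).shape)
    if np.ndim(s) == 0 and not np.iscomplexobj(s) and s == 1.0:
        if np.ndim(x) == 0 and x == 1.0:
            return 0.0
        method = "ode"  # z0(s) is singular at s = 1; h(1, u) = 1 is regular
    use_closed = method in ("auto", "closed") and _hyp_params(theta).ok
    if method == "closed" and not use_closed:
        raise _ClosedFormUnavailable(_hyp_params(theta).reason)
    if use_closed:
        try:
            out = _log_phi_closed(x, s, t, theta)
            if np.all(np.isfinite(np.real(out))):
                return out
            logger.debug("closed-form PGF returned non-finite values; "
                         "falling back to ODE quadrature")
        except _ClosedFormUnavailable:
            pass
        if method == "closed":
            raise _ClosedFormUnavailable("non-finite closed-form value")
    _, lp = _ode_psi_logphi(x, s, t, theta)
    out = lp if np.iscomplexobj(np.asarray(s)) else lp.real
    return out if np.asarray(s).ndim else out[0]


def immigration_pgf(s, t: float, theta: ModelParams, method: str = "auto"):
    """log G(s, t), the population cancer-compartment PGF (<= 0 on [0, 1])."""
    if theta.mu2 == 0:
        return np.zeros(np.shape(s)) if np.ndim(s) else 0.0
    return log_joint_pgf(1.0, s, t, theta, method=method)


def log_pgf_path(theta: ModelParams, t: float, path: np.ndarray,
                 variable: str = "s", x: float = 1.0, s: float = 0.0,
                 method: str = "auto"):
    """log PGF along an *ordered* complex path whose first point is real.

    Phase-unwraps the complex logarithm along the path so the result is the
    analytic branch (the closed form alone only returns the principal branch,
    which is wrong once mu1/b1 times the winding is non-integral).
    ``variable`` selects the free argument: "s" evaluates log G(path, t) (at
    x fixed), "x" evaluates log Phi(path, s, t) at fixed s.
    """
    path = np.asarray(path)
    use_closed = method in ("auto", "closed") and _hyp_params(theta).ok
    if use_closed:
        try:
            if variable == "s":
                K, C, D, pref = _kcd(theta, t, path)
                u = K / (C + D * x)
            else:
                K, C, D, pref = _kcd(theta, t, s)
                u = K / (C + D * path)
            mag = np.log(np.abs(u))
            ang = np.unwrap(np.angle(u))
            out = pref + theta.mu1 / theta.b1 * (mag + 1j * ang)
            if np.all(np.isfinite(mag)):
                return out
        except _ClosedFormUnavailable:
            pass
        if method == "closed":
            raise _ClosedFormUnavailable("closed-form path evaluation failed")
    if variable == "s":
        _, lp = _ode_psi_logphi(x, path, t, theta)
    else:
        _, lp = _ode_psi_logphi(path, np.full(path.shape, s, dtype=path.dtype),
                                t, theta)
    return lp


def exact_cdf_small(theta: ModelParams, t: float, N: int, *,
                    variable: str = "M", x: float = 1.0,
                    rho: float | None = None, method: str = "auto",
                    n_max_exact: int = N_MAX_EXACT) -> float:
    """P(M(t) <= N) (or, with variable="A0", sum_{k<=N} P(A=k, M=0)) by exact
    Cauchy-coefficient extraction of PGF(s)/(1-s) on a circle of radius rho.

    Trapezoidal quadrature over a power-of-two grid is an FFT; the radius
    defaults to min(0.95, e^{-15/N}) so the target coefficient times rho^N
    stays ~15 e-folds above double-precision roundoff.
    """
    if N < 0:
        return 0.0
    if N > n_max_exact:
        raise ValueError(f"N={N} above n_max_exact={n_max_exact}; "
                         "use the saddle-point CDF")
    if variable == "M" and theta.mu2 == 0:
        return 1.0
    if rho is None:
        rho = math.exp(-15.0 / max(N, 8))
    M = 1 << int(np.ceil(np.log2(max(8 * (N + 1), 512))))
    jj = np.arange(M // 2 + 1)
    sg = rho * np.exp(2j * np.pi * jj / M)
    if variable == "M":
        lg = log_pgf_path(theta, t, sg, variable="s", x=x, method=method)
    else:
        lg = log_pgf_path(theta, t, sg, variable="x", s=0.0, method=method)
    W = np.exp(lg) / (1.0 - sg)
    Wfull = np.concatenate([W, np.conj(W[-2:0:-1])])
    coef = np.fft.fft(Wfull) / M
    val = float((coef[N] / rho**N).real)
    resid = abs((coef[N] / rho**N).imag)
    if resid > 1e-6 * max(abs(val), 1e-12):  # pragma: no cover - guard
        raise RuntimeError(f"contour quadrature did not converge (imag {resid:.2e})")
    return min(max(val, 0.0), 1.0)
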