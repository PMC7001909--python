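"""Synchronous cancer risk given an adenoma finding.

The quantity of clinical interest is P(M(t) > 0 | A(t) in range) for a
screen-detected adenoma size range at age t.  By Bayes' theorem,

    P(M=0 | A in (k1, k2]) = P(A in range, M=0) / P(A in range).

The joint numerator has a remarkable closed form: with the M-argument fixed
at 0, the two-type PGF collapses to

    Phi(x, 0, t) = P(M(t)=0) * ((1 - q)/(1 - q x))^{mu1/b1},

i.e. the adenoma compartment *conditioned on no malignant cell* is again
negative binomial with the same dispersion r = mu1/b1 and a tilted success
probability q(t, theta) < p(t).  (In the hypergeometric representation
log Phi = pref + (mu1/b1) log(K/(C + D x)) the x-dependence is a single
algebraic factor, so q = -D/C.)  Both numerator and denominator are then
stable log-space negative-binomial bin probabilities at any size and age.

The adenoma-resistant fraction lambda only enters when the conditioning range
includes A = 0; conditioning on a *detected* adenoma (k >= 1) cancels it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .adenoma_dist import nb_bin_log_prob, nb_params
from .model_core import MixtureParam, ModelParams, mm_to_cells
from .pgf_engine import _ClosedFormUnavailable, _kcd

__all__ = ["RiskQuery", "joint_m0_nb", "p_no_cancer_given_A",
           "cancer_risk_given_adenoma", "risk_table"]

#: lower edge of the smallest reported-size bucket ("<5 mm" starts at 1 mm)
DEFAULT_MIN_MM = 1.0


@dataclass(frozen=True)
class RiskQuery:
    age: float
    theta: ModelParams
    size_lower_mm: float | None = None
    size_upper_mm: float | None = None
    lam: MixtureParam = field(default_factory=MixtureParam)

    def __post_init__(self) -> None:
        if self.size_lower_mm is None and self.size_upper_mm is None:
            raise ValueError("at least one size bound is required")
        if self.age <= 0:
            raise ValueError("age must be > 0")

    def cell_range(self) -> tuple[float, float]:
        lo = -1.0 if self.size_lower_mm in (None, 0, 0.0) else \
            float(mm_to_cells(self.size_lower_mm)) - 1.0
        hi = math.inf if self.size_upper_mm is None else \
            float(mm_to_cells(self.size_upper_mm))
        return lo, hi


def joint_m0_nb(theta: ModelParams, t: float):
    """(log P(M=0), r, q) of the exact P(A=k, M=0) = P(M=0) NB(k; r, q)
    representation (see module docstring)."""
    if theta.mu2 == 0:
        nb = nb_params(theta, t)
        return 0.0, nb.r, nb.p
    try:
        K, C, D, pref = _kcd(theta, t, 0.0)
    except _ClosedFormUnavailable:
        K = C = D = None
    if K is None or not np.isfinite(K):
        # degenerate hypergeometric parameterization: recover q from the ODE
        # route via the ratio Phi(x2)/Phi(x1) (two evaluations pin q exactly)
        from .pgf_engine import log_joint_pgf

        l0 = float(log_joint_pgf(1.0, 0.0, t, theta, method="ode"))
        sc = theta.mu1 / theta.b1
        l1 = float(log_joint_pgf(0.5, 0.0, t, theta, method="ode"))
        # l0 - l1 = sc * log((1 - 0.5 q)/(1 - q))
        g = math.exp((l0 - l1) / sc)
        q = (g - 1.0) / (g - 0.5)
        return l0, sc, q
    sc = theta.mu1 / theta.b1
    q = float(-D / C)
    log_m0 = pref + sc * math.log(float(K / (C + D)))
    return log_m0, sc, min(max(q, 0.0), 1.0 - 1e-15)


def p_no_cancer_given_A(theta: ModelParams, t: float, k: int,
                        deplete_denominator: bool = False) -> float:
    """P(M(t) = 0 | A(t) = k), evaluated in log space (stable at any k).

    ``deplete_denominator`` switches the Bayes denominator from the mu2 = 0
    adenoma marginal (the convention used in the fitting likelihood) to the
    exact full-model marginal with death rate d1 + mu2; the two differ by
    O(mu2/b1).
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    if t <= 0:
        raise ValueError("age must be > 0")
    if theta.mu2 == 0:
        return 1.0
    log_m0, sc, q = joint_m0_nb(theta, t)
    nb = nb_params(theta, t, deplete_by_mu2=deplete_denominator)
    log_num = log_m0 + float(stats.nbinom.logpmf(k, sc, 1.0 - q))
    log_den = float(stats.nbinom.logpmf(k, nb.r, 1.0 - nb.p))
    if not np.isfinite(log_den):
        raise ValueError(f"adenoma marginal mass vanishes at k={k}, t={t}")
    return min(math.exp(log_num - log_den), 1.0)


def cancer_risk_given_adenoma(query: RiskQuery,
                              deplete_denominator: bool = False) -> float:
    """P(M(t) > 0 | A(t) in the queried size range)."""
    theta, t = query.theta, query.age
    if theta.mu2 == 0:
        return 0.0
    lo, hi = query.cell_range()
    includes_zero = lo < 0
    log_m0, sc, q = joint_m0_nb(theta, t)
    nb = nb_params(theta, t, deplete_by_mu2=deplete_denominator)
    log_num = log_m0 + float(nb_bin_log_prob(sc, q, [lo], [hi])[0])
    log_den = float(nb_bin_log_prob(nb.r, nb.p, [lo], [hi])[0])
    if not np.isfinite(log_den):
        raise ValueError("conditioning range has (numerically) no adenoma mass")
    lam = query.lam.lam if includes_zero else 0.0
    if lam > 0.0:
        num = lam + (1.0 - lam) * math.exp(log_num)
        den = lam + (1.0 - lam) * math.exp(log_den)
        return min(max(1.0 - num / den, 0.0), 1.0)
    return min(max(-math.expm1(log_num - log_den), 0.0), 1.0)


def risk_table(theta: ModelParams, lam: MixtureParam | float,
               ages, mm_ranges, min_mm: float = DEFAULT_MIN_MM) -> pd.DataFrame:
    """Conditional cancer probability per (age, reported-size range).

    ``mm_ranges`` is an iterable of (low_mm, high_mm) pairs; ``high_mm`` may
    be None/inf for an open upper bound, and a low bound of 0/None starts the
    bucket at ``min_mm`` (a detected adenoma has a reported size of at least
    1 mm).
    """
    if not isinstance(lam, MixtureParam):
        lam = MixtureParam(lam=float(lam))
    rows = []
    for age in ages:
        for lo_mm, hi_mm in mm_ranges:
            lo_eff = min_mm if (lo_mm is None or lo_mm <= 0) else lo_mm
            hi_eff = None if (hi_mm is None or math.isinf(hi_mm)) else hi_mm
            q = RiskQuery(age=float(age), theta=theta, lam=lam,
                          size_lower_mm=lo_eff, size_upper_mm=hi_eff)
            rows.append({
                "age": float(age),
                "mm_low": float(lo_eff),
                "mm_high": math.inf if hi_eff is None else float(hi_eff),
                "probability": cancer_risk_given_adenoma(q),
            })
    return pd.DataFrame(rows)
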