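"""Stochastic simulation of the two-type branching process.

Three layers:

* :func:`gillespie_run` / :func:`gillespie_sample` -- exact stochastic
  simulation (Gillespie) of the six reactions

      0 -> A (mu1),  A -> 2A (b1 A),  A -> 0 (d1 A),
      A -> M (mu2 A),  M -> 2M (b2 M),  M -> 0 (d2 M).

* :func:`hybrid_cohort` -- cohort generator at realistic compartment sizes
  (~1e8 cells).  Because every propensity is linear, the adenoma compartment
  is advanced over each interval by sampling its *exact* transition law --
  binomial survival of the current cells, a negative-binomial offspring excess
  for the survivors, and an independent negative-binomial immigration
  component -- rather than by tau-leaping (whose O(tau) weak bias accumulates
  measurably over 80 years).  The cancer compartment is simulated exactly
  conditional on the A path: malignant clones are seeded from a Poisson
  process whose intensity interpolates mu2 A(t) across the step, and each
  clone's size at the assessment age is drawn from the exact single-clone
  birth-death law (an atom at 0 plus a geometric tail).  Naive tau-leaping of
  the M reactions would be badly biased at small M, where seeding and early
  extinction dominate.

* :func:`synth_registry` -- endoscopy-style and cancer-registry-style tables
  (ages, mm-binned sizes, zero findings, per-age incident/at-risk counts with
  censored prevalent cases) emulating the structure of the CORI and SEER
  extracts, with the generating parameters returned for recovery tests.

Defaults follow the biologically motivated simulation parameter set
mu1=3.1, b1=9, d1=8.8, mu2=1e-5, b2=9.2, d2=8.8 (per cell per year) with a
resistant fraction lambda=0.4.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .model_core import ModelParams, cells_to_mm, mm_to_cells

__all__ = ["SIM_PARAMS", "SIM_LAMBDA", "CohortSpec", "gillespie_run",
           "gillespie_sample", "single_clone_extinct_frequency",
           "hybrid_cohort", "cohort_to_observations", "synth_registry"]

#: the biologically motivated simulation parameter set
SIM_PARAMS = ModelParams(mu1=3.1, b1=9.0, d1=8.8, mu2=1e-5, b2=9.2, d2=8.8)
#: resistant (never-adenoma) population fraction used for the simulated fits
SIM_LAMBDA = 0.4


@dataclass(frozen=True)
class CohortSpec:
    n_individuals: int
    ages_to_record: tuple = tuple(range(4, 81, 4))
    lam: float = SIM_LAMBDA
    theta: ModelParams = SIM_PARAMS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if list(self.ages_to_record) != sorted(self.ages_to_record):
            raise ValueError("ages_to_record must be sorted")
        if not (0.0 <= self.lam <= 1.0):
            raise ValueError("lam must be in [0, 1]")


# ---------------------------------------------------------------------------
# exact Gillespie


@njit(cache=True)
def _gillespie_events(mu1, b1, d1, mu2, b2, d2, t_end, a0, m0, seed,
                      max_events):
    np.random.seed(seed)
    t = 0.0
    A = a0
    M = m0
    cap = min(max_events, 4_000_000)
    times = np.empty(cap + 1, dtype=np.float64)
    As = np.empty(cap + 1, dtype=np.int64)
    Ms = np.empty(cap + 1, dtype=np.int64)
    times[0], As[0], Ms[0] = 0.0, A, M
    n = 1
    n_events = 0
    while True:
        r_tot = mu1 + (b1 + d1 + mu2) * A + (b2 + d2) * M
        if r_tot <= 0.0:
            break
        t += np.random.exponential(1.0 / r_tot)
        if t >= t_end:
            break
        n_events += 1
        if n_events > max_events:
            return times[:n], As[:n], Ms[:n], -1  # guard tripped
        u = np.random.random() * r_tot
        if u < mu1:
            A += 1
        elif u < mu1 + b1 * A:
            A += 1
        elif u < mu1 + (b1 + d1) * A:
            A -= 1
        elif u < mu1 + (b1 + d1 + mu2) * A:
            A -= 1
            M += 1
        elif u < mu1 + (b1 + d1 + mu2) * A + b2 * M:
            M += 1
        else:
            M -= 1
        if n <= cap:
            times[n], As[n], Ms[n] = t, A, M
            n += 1
    return times[:n], As[:n], Ms[:n], 0


@njit(cache=True)
def _gillespie_at_time(mu1, b1, d1, mu2, b2, d2, t_end, a0, m0):
    # state at t_end only (rng state carried by the caller's np.random.seed)
    t = 0.0
    A = a0
    M = m0
    while True:
        r_tot = mu1 + (b1 + d1 + mu2) * A + (b2 + d2) * M
        if r_tot <= 0.0:
            break
        t += np.random.exponential(1.0 / r_tot)
        if t >= t_end:
            break
        u = np.random.random() * r_tot
        if u < mu1:
            A += 1
        elif u < mu1 + b1 * A:
            A += 1
        elif u < mu1 + (b1 + d1) * A:
            A -= 1
        elif u < mu1 + (b1 + d1 + mu2) * A:
            A -= 1
            M += 1
        elif u < mu1 + (b1 + d1 + mu2) * A + b2 * M:
            M += 1
        else:
            M -= 1
    return A, M


@njit(cache=True)
def _gillespie_sample_loop(mu1, b1, d1, mu2, b2, d2, t_end, a0, m0, n, seed):
    np.random.seed(seed)
    As = np.empty(n, dtype=np.int64)
    Ms = np.empty(n, dtype=np.int64)
    for i in range(n):
        A, M = _gillespie_at_time(mu1, b1, d1, mu2, b2, d2, t_end, a0, m0)
        As[i] = A
        Ms[i] = M
    return As, Ms


def gillespie_run(theta: ModelParams, t_end: float, seed: int,
                  a0: int = 0, m0: int = 0, max_events: int = 10**8):
    """One exact sample path; returns (event_times, A, M) arrays.

    Raises if the event guard is exceeded (use :func:`hybrid_cohort` /
    tau-leaping for desk-scale simulation of large compartments).
    """
    if any(r < 0 for r in theta.as_tuple()):
        raise ValueError("rates must be >= 0")
    t, A, M, status = _gillespie_events(*theta.as_tuple(), t_end, a0, m0,
                                        int(seed) % 2**31, int(max_events))
    if status < 0:
        raise RuntimeError(
            f"event guard ({max_events}) exceeded at t={t[-1]:.3f}; "
            "compartments too large for exact simulation - use tau-leaping "
            "(hybrid_cohort)")
    return t, A, M


def gillespie_sample(theta: ModelParams, t: float, n: int, seed: int,
                     a0: int = 0, m0: int = 0):
    """(A(t), M(t)) over n independent exact runs (end state only)."""
    return _gillespie_sample_loop(*theta.as_tuple(), t, a0, m0, int(n),
                                  int(seed) % 2**31)


def single_clone_extinct_frequency(theta: ModelParams, t: float, n: int,
                                   seed: int) -> float:
    """Monte-Carlo estimate of P(M(t)=0 | A(0)=1) with no immigration."""
    th = ModelParams(0.0, theta.b1, theta.d1, theta.mu2, theta.b2, theta.d2)
    _, Ms = gillespie_sample(th, t, n, seed, a0=1)
    return float(np.mean(Ms == 0))


# ---------------------------------------------------------------------------
# hybrid simulation: exact/tau-leap A, conditionally exact M clones


@njit(cache=True)
def _clone_size_at(b2, d2, tau, u1, u2):
    """Exact single-clone birth-death size after time tau (two uniforms)."""
    if tau <= 0.0:
        return 1
    g2 = b2 - d2
    if abs(g2) > 1e-12:
        e = math.exp(g2 * tau)
        alpha = d2 * (e - 1.0) / (b2 * e - d2)   # extinction probability
        beta = b2 * alpha / d2 if d2 > 0 else b2 * (e - 1.0) / (b2 * e - d2)
    else:
        alpha = b2 * tau / (1.0 + b2 * tau)
        beta = alpha
    if u1 < alpha:
        return 0
    if beta <= 0.0:
        return 1
    # P(Z=k | Z>0) = (1-beta) beta^{k-1}
    k = 1 + int(math.log(u2) / math.log(beta)) if u2 > 0.0 else 1
    return k


@njit(cache=True)
def _binom_draw(n, q):
    """Binomial(n, q) sample: explicit loop for small n, Gaussian otherwise
    (n q (1-q) is large in every branch that reaches it here)."""
    if n <= 0 or q <= 0.0:
        return 0
    if q >= 1.0:
        return n
    if n <= 1000:
        k = 0
        for _ in range(n):
            if np.random.random() < q:
                k += 1
        return k
    m = n * q
    v = n * q * (1.0 - q)
    k = int(round(m + math.sqrt(v) * np.random.standard_normal()))
    return min(max(k, 0), n)


@njit(cache=True)
def _nb_draw(r, p):
    """Negative binomial NB(r, p) (support 0, 1, ...) via gamma-Poisson."""
    if r <= 0.0 or p <= 0.0:
        return 0
    lam = np.random.gamma(r, p / (1.0 - p))
    if lam > 1e15:  # CLT on the Poisson stage far beyond int sampling range
        return int(lam + math.sqrt(lam) * np.random.standard_normal())
    return np.random.poisson(lam)


@njit(cache=True)
def _step_A_exact(A, b, d, mu1, tau):
    """Exact one-step transition of a linear birth-death-immigration count.

    A(t+tau) | A(t) = Binomial survivors + NB offspring excess + NB immigrant
    component (each immigrant clone integrated over its arrival time).
    """
    g = b - d
    if abs(g) > 1e-12 * max(b, d, 1.0):
        e = math.exp(g * tau)
        alpha = d * (e - 1.0) / (b * e - d)
        beta = b * alpha / d if d > 0 else 1.0 - 1.0 / e
        p_imm = b * (e - 1.0) / (b * e - d)
    else:
        alpha = b * tau / (1.0 + b * tau)
        beta = alpha
        p_imm = alpha
    if A >= 1_000_000:
        # full-transition CLT (relative skew ~ A^{-1/2} < 1e-3)
        e = math.exp(g * tau)
        v1 = (b + d) / g * e * (e - 1.0) if abs(g) > 1e-12 else 2.0 * b * tau
        m_imm = mu1 * (e - 1.0) / g if abs(g) > 1e-12 else mu1 * tau
        r_imm = mu1 / b if b > 0 else 0.0
        v_imm = r_imm * p_imm / (1.0 - p_imm) ** 2
        mean = A * e + m_imm
        var = A * v1 + v_imm
        out = int(round(mean + math.sqrt(var) * np.random.standard_normal()))
        return max(out, 0)
    n_surv = _binom_draw(A, 1.0 - alpha)
    total = n_surv
    if n_surv > 0:
        total += _nb_draw(float(n_surv), beta)
    if mu1 > 0.0 and b > 0.0:
        total += _nb_draw(mu1 / b, p_imm)
    return total


@njit(cache=True)
def _hybrid_individual(mu1, b1, d1, mu2, b2, d2, t_obs, dt):
    """(A, M) at t_obs; A by exact interval sampling, M by conditional
    clone seeding (trapezoidal seed intensity across each step)."""
    t = 0.0
    A = 0
    M = 0
    d_eff = d1 + mu2  # conversion removes the cell from compartment A
    while t < t_obs - 1e-12:
        tau = min(dt, t_obs - t)
        A_new = _step_A_exact(A, b1, d_eff, mu1, tau)
        if mu2 > 0.0:
            seeds = np.random.poisson(mu2 * 0.5 * (A + A_new) * tau)
            for _ in range(seeds):
                ts = t + np.random.random() * tau
                M += _clone_size_at(b2, d2, t_obs - ts,
                                    np.random.random(), np.random.random())
        A = A_new
        t += tau
    return A, M


@njit(cache=True)
def _hybrid_cohort_loop(mu1, b1, d1, mu2, b2, d2, t_obs_arr, resistant,
                        dt, seed):
    np.random.seed(seed)
    n = t_obs_arr.shape[0]
    As = np.zeros(n, dtype=np.int64)
    Ms = np.zeros(n, dtype=np.int64)
    for i in range(n):
        if resistant[i]:
            continue
        A, M = _hybrid_individual(mu1, b1, d1, mu2, b2, d2, t_obs_arr[i], dt)
        As[i] = A
        Ms[i] = M
    return As, Ms


def hybrid_cohort(spec: CohortSpec, dt: float = 0.25) -> pd.DataFrame:
    """Simulate a cohort; each individual is assessed at one age drawn
    uniformly from ``spec.ages_to_record``.

    Returns a DataFrame with columns individual, age, A, M; a fraction
    ``lam`` of individuals is adenoma-resistant (A = M = 0 at every age).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_individuals
    ages = rng.choice(np.asarray(spec.ages_to_record, dtype=float), size=n)
    resistant = rng.random(n) < spec.lam
    As, Ms = _hybrid_cohort_loop(*spec.theta.as_tuple(), ages, resistant,
                                 dt, int(rng.integers(2**31)))
    return pd.DataFrame({"individual": np.arange(n), "age": ages,
                         "A": As, "M": Ms, "resistant": resistant})


#: factor-two reported-size bin edges (mm) for compartment-M observations
M_SIZE_EDGES_MM = (0.5, 1.5, 3.5, 7.5, 15.5, 31.5, 63.5, 127.5)


def cohort_to_observations(cohort: pd.DataFrame, a_detect_mm: float = 0.5,
                           m_detect_mm: float = 0.5) -> list:
    """Convert simulated (age, A, M) rows into size-binned observations.

    Compartment A: reported size = nearest integer mm (0 below
    ``a_detect_mm``), binned +-0.5 mm.  Compartment M: detection below
    ``m_detect_mm`` yields a zero-inclusive bin; detected cancers fall into
    factor-two mm bins (``M_SIZE_EDGES_MM``), which keeps the number of
    distinct likelihood bins per age small.
    """
    from .model_core import Observation, bin_from_report

    edges_cells = [float(mm_to_cells(e)) for e in M_SIZE_EDGES_MM]
    m_zero_hi = float(mm_to_cells(m_detect_mm))
    out = []
    mm_a = cells_to_mm(cohort["A"].to_numpy(dtype=float))
    reported_a = np.where(mm_a >= a_detect_mm, np.round(mm_a), 0.0)
    Mv = cohort["M"].to_numpy(dtype=float)
    ages = cohort["age"].to_numpy(dtype=float)
    for age, ra, m in zip(ages, reported_a, Mv):
        lo, hi = bin_from_report(float(ra))
        out.append(Observation("A", float(age), lo, hi))
        if m < m_zero_hi:
            out.append(Observation("M", float(age), -1.0, m_zero_hi))
        else:
            j = int(np.searchsorted(edges_cells, m, side="right"))
            lo_m = edges_cells[j - 1]
            hi_m = edges_cells[j] if j < len(edges_cells) else math.inf
            out.append(Observation("M", float(age), lo_m, hi_m))
    return out


# ---------------------------------------------------------------------------
# registry-style synthetic tables


@njit(cache=True)
def _registry_loop(mu1, b1, d1, mu2, b2, d2, n, t_end, colo_ages, resistant,
                   thr_cells, dt, seed):
    """Per individual: A at the colonoscopy age and the first age at which a
    malignant clone crosses thr_cells (inf if never by t_end).

    Clone crossing times use the supercritical birth-death limit
    Z(tau) ~ W e^{g2 tau}: a seed survives with probability g2/b2, in which
    case W ~ Exp(mean b2/g2) and the crossing time is ts + log(thr/W)/g2.
    """
    np.random.seed(seed)
    g2 = b2 - d2
    p_surv = g2 / b2 if g2 > 0 else 0.0
    d_eff = d1 + mu2
    A_colo = np.zeros(n, dtype=np.int64)
    crossing = np.full(n, np.inf)
    for i in range(n):
        if resistant[i]:
            continue
        t = 0.0
        A = 0
        cross = np.inf
        recorded = colo_ages[i] <= 0.0
        while t < t_end - 1e-12:
            tau = min(dt, t_end - t)
            if not recorded and colo_ages[i] > t:
                tau = min(tau, colo_ages[i] - t)
            A_new = _step_A_exact(A, b1, d_eff, mu1, tau)
            if mu2 > 0.0 and p_surv > 0.0:
                seeds = np.random.poisson(
                    mu2 * 0.5 * (A + A_new) * tau * p_surv)
                for _ in range(seeds):
                    ts = t + np.random.random() * tau
                    W = np.random.exponential(b2 / g2)
                    c = ts + math.log(thr_cells / W) / g2 if W > 0 else np.inf
                    if c < cross:
                        cross = c
            A = A_new
            t += tau
            if not recorded and t >= colo_ages[i] - 1e-12:
                A_colo[i] = A
                recorded = True
        crossing[i] = cross
    return A_colo, crossing


def synth_registry(spec: CohortSpec, detect_mm: float = 0.5,
                   max_age: int = 60, colo_age_range=(40.0, 50.0),
                   diagnosis_delay_yr: float = 0.5,
                   adenoma_max_mm: float = 40.0):
    """Synthetic endoscopy-like and cancer-registry-like tables.

    Returns (adenoma_df, registry_df, tumor_df, truth) where

    * adenoma_df: one screening colonoscopy per individual at an age uniform
      on ``colo_age_range``: columns age, size_mm (0 = normal finding);
    * registry_df: per integer age, incident cancer count and at-risk count
      (individuals already incident are censored from follow-up);
    * tumor_df: mm sizes of incident tumors at diagnosis;
    * truth: dict with the generating parameters and the true censored
      prevalent count per age (for round-trip tests).

    ``detect_mm = inf`` disables cancer detection entirely.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_individuals
    colo_ages = rng.uniform(*colo_age_range, size=n)
    resistant = rng.random(n) < spec.lam
    thr = float(mm_to_cells(detect_mm)) if math.isfinite(detect_mm) else math.inf
    g2 = spec.theta.gamma2
    if math.isinf(thr):
        # adenoma sizes still needed: run with an unreachable threshold
        A_colo, crossing = _registry_loop(
            *spec.theta.as_tuple(), n, float(max_age), colo_ages, resistant,
            1e300, 0.25, int(rng.integers(2**31)))
        crossing[:] = np.inf
    else:
        A_colo, crossing = _registry_loop(
            *spec.theta.as_tuple(), n, float(max_age), colo_ages, resistant,
            thr, 0.25, int(rng.integers(2**31)))

    # endoscopy table: reported mm (0 below detect_mm resolution / 1 mm)
    mm = cells_to_mm(np.maximum(A_colo, 0).astype(float))
    reported = np.where(mm >= 1.0, np.minimum(np.round(mm), adenoma_max_mm),
                        0.0)
    adenoma_df = pd.DataFrame({"age": colo_ages, "size_mm": reported})

    # registry: diagnosis shortly after crossing; censored afterwards
    delay = rng.uniform(0.0, diagnosis_delay_yr, size=n)
    diag_age = crossing + delay
    ages = np.arange(0, max_age)
    inc = np.zeros(len(ages), dtype=np.int64)
    at_risk = np.zeros(len(ages), dtype=np.int64)
    prevalent_true = np.zeros(len(ages), dtype=np.int64)
    for j, a in enumerate(ages):
        inc[j] = int(np.sum((diag_age >= a) & (diag_age < a + 1)))
        at_risk[j] = int(np.sum(diag_age >= a + 1))
        prevalent_true[j] = int(np.sum(diag_age < a))
    registry_df = pd.DataFrame({"age": ages, "incident_count": inc,
                                "at_risk_count": at_risk})
    diagnosed = np.isfinite(diag_age) & (diag_age < max_age)
    size_at_diag = thr * np.exp(g2 * delay[diagnosed]) if np.any(diagnosed) \
        else np.array([])
    tumor_df = pd.DataFrame({
        "age": diag_age[diagnosed],
        "size_mm": np.round(cells_to_mm(size_at_diag)* 2) / 2 if len(size_at_diag)
        else np.array([]),
    })
    truth = {"theta": spec.theta, "lam": spec.lam,
             "prevalent_true": prevalent_true, "ages": ages}
    return adenoma_df, registry_df, tumor_df, truth
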