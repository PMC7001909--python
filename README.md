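# crcbp — two-type branching-process model of colorectal cancer progression

Colorectal carcinoma develops from benign adenomatous polyps, but the rates
governing that progression — how fast adenomas grow, how often an adenoma
cell turns malignant, how fast an early carcinoma expands — cannot be
measured directly, because detected adenomas are removed.  `crcbp` implements
a two-type continuous-time branching process that makes these rates
estimable from routinely collected screening data: endoscopy registries
record adenoma sizes and normal colonoscopies; cancer registries record
incident carcinoma sizes and at-risk counts.

**Model.**  Adenoma cells (compartment *A*) arrive from the colonic-crypt
stem-cell pool at rate μ₁ (cells/year), divide at b₁ and die at d₁ (per cell
per year), and seed malignant cells (compartment *M*) at rate μ₂; malignant
cells divide at b₂ and die at d₂.  Net growth rates are γ₁ = b₁ − d₁ and
γ₂ = b₂ − d₂.  A fraction λ of the population never develops adenomas
(zero-inflation).  Reported lesion sizes (largest dimension, mm) map to cell
counts as half-ellipsoid volumes at 10⁸ cells/cm³.

**What the package computes.**

- The adenoma size law: A(t) is negative binomial with r = μ₁/b₁ and
  p(t) = b₁(e^{γ₁t} − 1)/(b₁e^{γ₁t} − d₁); binned likelihoods are
  regularized-incomplete-beta tail differences, evaluated stably in log
  space arbitrarily far into both tails.
- The carcinoma size distribution: the probability generating function
  G(s,t) of M(t) is solved in closed form (Gauss hypergeometric functions,
  with a branch-free Riccati-ODE route as oracle and fallback), and
  P(M(t) ≤ N) is extracted as a Cauchy coefficient of G(s,t)/(1−s) — exactly
  by FFT for small N, and for arbitrary N by saddle-point-localized contour
  quadrature, accurate to ≲10⁻⁴ where exact values exist for comparison.
  The textbook leading-order stationary-phase formula
  e^{V(s*)}/√(2πV″(s*)) is also provided for reference.
- Composite inference: a weighted composite log-likelihood over size-binned
  observations from both compartments with the λ mixture, Nelder–Mead MLE,
  observed-information intervals, likelihood-surface grids, and an adaptive
  Metropolis sampler targeting 30% acceptance.
- Individualized risk: P(cancer present | adenoma of a given size at a given
  age), via the exact identity that A conditioned on M = 0 is again negative
  binomial with a tilted success probability.
- Simulation: exact Gillespie for validation, and a fast cohort generator
  that samples the adenoma compartment's exact interval transition law and
  the malignant clones' exact conditional size law — unbiased at realistic
  (10⁸-cell) compartment sizes.  Registry-style synthetic tables (incident /
  at-risk counts with censored prevalent cases) and the prevalence-imputation
  recursion P(t) = I(t)·P̂(t)/Î(t) complete the data pipeline.

## Worked example

```python
import numpy as np
from crcbp import (SIM_PARAMS, CohortSpec, FitParams, ObsData, RiskQuery,
                   cancer_risk_given_adenoma, cohort_to_observations,
                   hybrid_cohort, mle_fit, mm_to_cells, cells_to_mm)

# a reported 10 mm adenoma corresponds to ~2.6e7 cells
mm_to_cells(10.0)                       # -> 26179939

# simulate a screening cohort at the biologically motivated rates
# (mu1=3.1, b1=9, d1=8.8, mu2=1e-5, b2=9.2, d2=8.8; resistant fraction 0.4)
cohort = hybrid_cohort(CohortSpec(n_individuals=4000, lam=0.4, seed=0))
obs = ObsData(cohort_to_observations(cohort))

# staged fit: adenoma compartment first, then the malignant parameters
init = FitParams(mu1=6.0, ratio=0.6, gamma1=0.12, mu2=3e-6, gamma2=0.6, lam=0.2)
odA = ObsData([o for o in cohort_to_observations(cohort) if o.compartment == "A"])
stage1, _ = mle_fit(odA, init, fix=("mu2", "gamma2"))
best, _ = mle_fit(obs, stage1, fix=("mu1", "ratio", "gamma1", "lam"))
```

prints (recovered vs generating values):

```
gamma1 = 0.199  (generating 0.2)
lambda = 0.402  (generating 0.4)
mu2    = 1.05e-05 (generating 1.0e-05)
gamma2 = 0.390  (generating 0.4)
```

The synchronous-cancer risk given an adenoma finding:

```python
for lo, hi in [(100, 1000), (2500, 25000), (50000, 500000)]:
    q = RiskQuery(age=50.0, theta=SIM_PARAMS,
                  size_lower_mm=cells_to_mm(lo), size_upper_mm=cells_to_mm(hi))
    print(lo, hi, cancer_risk_given_adenoma(q))
```

```
P(cancer | 100-1000 adenoma cells, age 50) = 0.0024
P(cancer | 2500-25000 adenoma cells, age 50) = 0.0537
P(cancer | 50000-500000 adenoma cells, age 50) = 0.5798
```

These conditional probabilities agree with empirical frequencies from exact
stochastic simulation (see `tests/test_acceptance.py`).  A command-line
interface (`crcbp simulate / prep / fit / mcmc / risk / surface`) wraps the
same functionality; every run writes a JSON manifest with its configuration
and seed.

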