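# Methods

## Model

The package models colorectal cancer natural history as a two-type branching
process with immigration.  Adenoma cells (*A*) are initiated from a static
stem-cell pool at rate μ₁ per year; each A cell divides at rate b₁, dies at
rate d₁, and converts to a malignant cell (*M*) at rate μ₂ (per cell per
year); each M cell divides at b₂ and dies at d₂.  Net growth rates are
γ₁ = b₁ − d₁ and γ₂ = b₂ − d₂.  All rates are constant in time and shared
across the population except for a resistant fraction λ that never develops
adenomas.  The model tracks compartment totals only: no spatial or
per-lesion structure, no multiple synchronous lesions, no time-varying
rates, no interaction between M cells and the rest of the system.

Reported lesion sizes (endoscopist-estimated largest dimension d, mm)
convert to cell counts as half-ellipsoid volumes with all three semi-axes
d/2 at 10⁸ cells/cm³: N(d) = 10⁸·(π/12)·(d/10)³, rounded half up.  This
convention, together with the fitted rates γ₁ = 0.165/yr and γ₂ = 1.76/yr,
reproduces the derived growth timings (21.9 years for 3→10 mm, 20.0 years
for 10→30 mm, under 7.35 years from one cell to 2.5 mm); the axis ratio is a
single documented constant and can be swapped.

## Adenoma compartment

With μ₂ = 0 the A compartment is a linear birth–death–immigration process
and A(t) is negative binomial with dispersion r = μ₁/b₁ and success
probability p(t) = b₁(e^{γ₁t} − 1)/(b₁e^{γ₁t} − d₁) (limit p = b₁t/(1+b₁t)
at γ₁ = 0).  Binned likelihoods P(L < A ≤ U) are regularized-incomplete-beta
tail differences.  Two numerical choices matter:

- bins are half-open (L, U] on integer counts; a zero-inclusive bin (normal
  colonoscopy, undetected cancer) is encoded with L = −1 so the mixture
  branch is decidable from the bin alone;
- where the beta-tail difference underflows (a bin many orders of magnitude
  from the bulk under a displaced optimizer iterate), the bin probability is
  rebuilt in log space from the log-pmf with a geometric tail-sum
  correction.  Without this the likelihood surface is −∞ in large regions
  and derivative-free optimization stalls at its starting point.

The exact A marginal of the full model has death rate d₁ + μ₂ (conversion
removes the cell from A).  The fitting likelihood deliberately uses the
μ₂ = 0 marginal — the difference is O(μ₂/b₁) ≈ 10⁻⁶ at realistic rates —
and a `deplete_by_mu2` switch selects the exact marginal where exactness
matters (oracle comparisons, simulation benchmarks).

## Cancer compartment: generating function

The joint single-clone PGF ψ(x, s, u) = E[x^{A(u)}s^{M(u)} | A(0)=1]
satisfies the backward Kolmogorov Riccati equation
ψ′ = b₁ψ² − (b₁+d₁+μ₂)ψ + d₁ + μ₂h(s,u), ψ(0) = x, where h is the standard
linear birth–death clone PGF.  Poisson immigration then gives
log Φ(x,s,t) = μ₁∫₀ᵗ(ψ − 1)du and G(s,t) = Φ(1,s,t).

Substituting z = z₀e^{−γ₂u} with z₀ = (d₂ − b₂s)/(b₂(1 − s)) linearizes the
Riccati equation into a Gauss hypergeometric equation.  With
w_i(z) = z^{ρ_i}·₂F₁(α_i, β_i; c_i; z) built from the indicial roots ρ_{1,2}
of ρ² − (a/γ₂)ρ + b₁(d₁ + μ₂d₂/b₂)/γ₂² (a = b₁+d₁+μ₂), the clone PGF is
ψ = (γ₂/b₁)z·w′/w and the immigration integral telescopes:

    log Φ = μ₁[(1/b₁)·log(w(z₀)/w(z_t)) − t]
          = pref + (μ₁/b₁)·log( K(s) / (C(s) + D(s)·x) ),

where K, C, D are combinations of six ₂F₁ values and the x-dependence is a
single Möbius factor (x only enters the initial condition).  Two useful
exact consequences:

- **A | M = 0 is negative binomial.**  At s = 0 the Möbius form means
  Φ(x,0,t) = P(M=0)·((1−q)/(1−qx))^{μ₁/b₁} with q = −D/C: the adenoma
  compartment conditioned on no malignant cell is again NB with the same
  dispersion and a tilted success probability.  The entire conditional-risk
  module runs on stable log-space NB arithmetic at any size and age; the
  representation is verified against a truncated-master-equation oracle and
  against contour-coefficient extraction to ~10⁻¹⁰.
- The μ₂ = 0 and μ₁ = 0 limits collapse to the expected identities
  (G ≡ 1; f ≡ 1), which pin the indicial-root bookkeeping.

A branch-free ODE route (direct integration of the Riccati system plus the
running integral, with analytic first and second s-derivatives) serves as
the independent oracle; the two routes agree to ≤10⁻⁶ relative on a broad
(s, t) grid, and the closed form falls back to the ODE automatically when
the hypergeometric parameterization degenerates (γ₂ ≈ 0, b₂ = 0, complex or
near-integer indicial exponents, overflow at extreme parameter corners).

## Cancer compartment: size CDF

P(M(t) ≤ N) is the N-th Taylor coefficient of G(s,t)/(1−s),

    P(M(t) ≤ N) = (1/2πi)∮ e^{V(s)} ds,
    V(s) = −log(1−s) + log G(s,t) − (N+1)·log s.

V is strictly convex on (0,1) ((log G)″ ≥ 0 for any PGF), so the saddle
V′(s*) = 0 is unique; it is found by a vectorized safeguarded Newton
iteration with finite differences taken in ζ = −log(1−s) (the saddle sits
within (1−s) ~ 1/N of 1 in the pole-dominated regime, where a raw-s stencil
collapses into roundoff).  Public second derivatives use Cauchy-integral
differentiation of the closed form on a small ring (spectral accuracy),
cross-checked against the analytically differentiated ODE system.

Evaluation of the contour integral:

- **Exact (N ≤ 2000):** trapezoidal quadrature on a circle = FFT, radius
  ρ = e^{−15/N} so the target coefficient stays ~15 e-folds above roundoff.
  The closed form on the circle needs branch tracking of the complex
  logarithm (G = exp((μ₁/b₁)·log(·)) with non-integral exponent); the phase
  is unwrapped along the contour, and the branch-free ODE route provides an
  independent check.
- **Saddle-point quadrature (any N, the default):** the circle through s*
  is integrated over the window |θ| ≤ 80σ (σ the stationary-phase width)
  with a cos² taper on the outer half.  The taper suppresses the boundary
  terms of non-stationary spectral components, which otherwise leak an
  O(1/(Nw)) error through a sharp cutoff.  In the pole-dominated regime
  (N beyond the bulk, CDF → its limit) the simple pole's coefficient is
  split off exactly, CDF = F(1) + [s^N]{(F−F(1))/(1−s)}, leaving an
  analytic kernel.  Accuracy is ≤10⁻⁴ relative against the exact FFT
  everywhere it can be compared (1% is the documented contract), and the
  CDF is monotone in N and in age across twelve decades of N.
- **Leading-order Gaussian formula** e^{V(s*)}/√(2πV″(s*)): retained as
  `method="gaussian"`.  Because the 1/(1−s) pole always sits about one
  Gaussian width from s*, this formula carries an intrinsic,
  non-vanishing relative inflation — exactly e/√(2π) ≈ 1.084 in the
  pure-pole limit G ≡ 1, about 5–8% for the heavy-tailed size laws arising
  here — so it is clipped to [0,1] and not used in the likelihood.  The
  saddle-localized quadrature is the same stationary-phase construction
  carried out numerically instead of to leading order.

Binned compartment-M likelihoods are CDF differences floored at zero; below
100 cells the CDF switches to the exact FFT (configurable), and a 10⁻²²⁰
floor keeps displaced optimizer iterates on a finite surface.

## Inference

The searched vector is (μ₁, μ₁/b₁, γ₁, μ₂, γ₂), optionally λ; death rates
are tied, d₂ = d₁, since (b₂, d₂) are not separately identifiable from size
data once γ₂ is fixed (an explicit d₂ can be supplied instead).  The
composite log-likelihood sums weighted per-bin log-terms of both
compartments, each passed through the zero-inflation mixture
λ + (1−λ)·L for zero-containing bins.  It is a *composite* likelihood — the
A and M rows of one individual are treated as independent although they are
correlated through the shared A history — so each term is a correct marginal
probability (estimates are consistent) but the curvature slightly overstates
the information; posterior intervals should be read with that caveat.

Optimization is Nelder–Mead in log-parameter space (logit for λ).  The
practical fitting recipe, used by the acceptance script, is staged: fit
(μ₁, μ₁/b₁, γ₁, λ) on the A rows alone, then (μ₂, γ₂) on the full set, then
release everything.  Uncertainty comes from Wald intervals on the observed
information and from an adaptive random-walk Metropolis chain: diagonal
proposal, global scale following a Robbins–Monro recursion targeting 30%
acceptance, per-coordinate scales tracking the chain's running spread,
all adaptation frozen after the first half of the chain; reported modes are
highest-posterior chain states and intervals are chain quantiles.

Lognormal priors on μ₁ (median 3,100, log-sd 1/25) and b₁ (median 9,
log-sd 1/3) are available but off by default: they encode biological
plausibility for registry-style fits, and the quoted "mean / standard
deviation" pairs are interpreted as median and sd of the natural log (the
only reading under which both densities are well-defined).  They are not
applied to synthetic-data fits, whose generating μ₁ = 3.1 they would
exclude.

A prevalence-only Bernoulli likelihood (cancer yes/no with
P(M>0) = (1−λ)(1−G(0,t))) is provided for the identifiability contrast: over
a 100-fold range of μ₂ its compensating γ₂ sweeps the entire admissible
range (an unidentified ridge in the (μ₂, γ₂) — equivalently (μ₂, b₂) —
plane), whereas the size-based likelihood pins γ₂ within a narrow band and
its grid maximum sits at the generating cell.

## Synthetic data generator

`hybrid_cohort` emulates the study conditions: n individuals, each assessed
at one age drawn uniformly from a grid (default every 4 years to 80), a
resistant fraction λ = 0.4, and the biologically motivated rates μ₁ = 3.1,
b₁ = 9, d₁ = 8.8, μ₂ = 10⁻⁵, b₂ = 9.2, d₂ = 8.8 as defaults.  Because all
propensities are linear, the A compartment is advanced by sampling its
*exact* interval transition law — binomial survival of existing cells, a
negative-binomial offspring excess, and a negative-binomial immigration
component — rather than by tau-leaping, whose O(τ) weak bias compounds to a
measurable (~3%) distortion of P(M=0) over 80 years.  Malignant clones are
seeded from a Poisson process whose intensity interpolates μ₂A(t) across
each step (trapezoid; relative error (γ₁τ)²/12 ≈ 2×10⁻⁴ at the default
τ = 0.25 yr), and each clone's size at the assessment age is drawn from the
exact single-clone birth–death law (atom at extinction plus a geometric
tail).  The A marginal is therefore exactly negative binomial and the
M marginal matches the generating-function CDF within Monte-Carlo error at
every size checked (z ≤ 1.2 at 30,000 replicates) — the simulator and the
analytic machinery validate each other.

Observations are binned as a registry would report them: adenomas at
integer-mm resolution (reported 0 below 0.5 mm), cancers into factor-two mm
bins above a 0.5 mm detection cut, with sub-threshold cancers contributing
zero-inclusive bins.  The coarse cancer bins keep the number of distinct
likelihood evaluations per age small; they are a deliberate aggregation
choice of the synthetic study, not a model feature.

What the generator does *not* emulate: detection sensitivity varying with
size or location, multiple lesions per patient, inter-individual rate
heterogeneity, secular trends, or reporting errors.  Passing recovery tests
therefore demonstrates correctness of the likelihood machinery under the
model's own assumptions, not robustness to real-data artifacts.

`synth_registry` additionally produces endoscopy-style and cancer-registry
tables: one screening colonoscopy per individual at ages 40–50, and per-age
incident/at-risk counts where a cancer is "incident" when its largest clone
crosses a detection size and the individual is censored afterwards.  Clone
crossing times use the supercritical limit Z(τ) ≈ We^{γ₂τ} (survival
probability γ₂/b₂, W | survival exponential with mean b₂/γ₂), a deliberate
large-threshold approximation labelled as such.  The prevalence-imputation
recursion (anchored R̂ = 1 at the youngest observed age, which the source
material leaves unstated) is scale-invariant, satisfies
P̂ + Î + R̂ = 1 exactly, and recovers the generator's true censored
prevalent counts within sampling error.

## Problem sizes and numerical defaults

Acceptance-scale runs use ~10,000 binned adenoma observations for the
A-only recovery and a 20,000-individual cohort with a 1,500-step adaptive
chain for the joint recovery; the test suite uses an 8,000-individual cohort
and a 1,000-step chain.  Likelihood evaluations inside optimization use the
faster quadrature setting (40σ window, 320 nodes; ≤6×10⁻⁴ relative error),
standalone CDF calls the default (80σ, 768 nodes; ≤10⁻⁴).  Exact-CDF FFTs
cap at N = 2000; the saddle/exact handover sits at 100 cells.  All random
draws flow from explicit integer seeds; simulator outputs are
bit-reproducible given the seed.

## Known limitations

- The composite likelihood's interval calibration is optimistic (see above).
- The leading-order Gaussian CDF formula is reported but intentionally not
  used for inference; its 5–8% bias is structural, not a tuning issue.
- Conditional risks for ranges deep outside the model's bulk (e.g. a 35 mm
  adenoma at age 1) are well-defined in log space but scientifically
  extrapolative.
- The registry generator's clone-crossing approximation slightly blurs
  incidence ages for detection thresholds below ~100 cells.
- Fits constrain d₂ = d₁; data carrying genuine information about b₂ and d₂
  separately (e.g. regression/remission dynamics) are outside the model.
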