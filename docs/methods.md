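# Methods

## Model

Two diseases are observed on a lattice of I areas x 2 genders x J age
groups.  Counts are conditionally Poisson with mean `n * r` (population at
risk times rate).  The package's model family factors the log-rate into
per-disease intercepts, a latent spatial surface shared between the
diseases, a disease-specific unstructured deviation, and age(-gender)
effects; `ModelSpec` switches each axis:

* `shared_spatial`: `none` | `common` | `by_gender`.  The surface enters
  disease 1 multiplied by `delta` and disease 2 by `1/delta`; `delta`
  measures how much more strongly the common risk factors express in the
  abundant disease.
* `specific_unstructured`: which diseases carry an iid normal area effect
  `u` (the selected model gives it to the sparse disease only, capturing
  where that disease departs from the shared pattern).
* `age_effect`: `none` | `by_age` | `by_age_gender`.
* `intercepts`: per-disease fixed levels.

The shared surface has an intrinsic CAR (Besag) prior: precision
`tau_kappa * R` per gender block, where `R` is the graph structure matrix
(degrees on the diagonal, -1 per neighbour pair).  `R` is rank-deficient by
one per connected component; the prior is therefore improper and the model
is identified by sum-to-zero constraints per gender (and per component).
The age-gender block `eta` is iid normal; because its overall level is
confounded with the intercepts, it is constrained to sum to zero overall.
`u` is proper iid normal and needs no constraint — shrinkage to zero
identifies it against the sparse disease's intercept.

Conventions worth stating once: every `tau` in the package is a
*precision*; equal-tailed 95% intervals by sample percentile with linear
interpolation; rates and spatial patterns are reported per 100,000
(`exp(kappa)*1e5`, `exp(u)*1e5`).

## Priors

* Precisions: penalised-complexity prior by default — exponential on the
  standard deviation `sigma = tau^-1/2` calibrated by `P(sigma > U) =
  alpha`, with `U = 1, alpha = 0.01` for all three precisions unless
  overridden.  The prior is weakly informative at the scale of log-rate
  effects (it says standard deviations above 1 on the log scale — an
  e-fold of rate variation — are improbable a priori).  Alternatives for
  sensitivity analysis: improper uniform on `sigma` (`p(tau) ∝ tau^-1.5`)
  and `tau ~ Gamma(a, b)` (default `(1, 5e-5)`).
* `log delta ~ logGamma(10, 10)`, i.e. `delta ~ Gamma(10, 10)`: mean 1,
  sd ~0.32 — the two diseases are a priori exchangeable in their loading.
* Intercepts: `N(0, precision 0.001)`.  A `("loggamma", (a, b))` option
  makes an intercept-only model exactly conjugate (`exp(alpha) ~
  Gamma(a, b)`), which the test suite uses as a closed-form oracle.

## Posterior computation

Sampling is Metropolis-within-Gibbs with three kinds of update per
iteration:

1. **Latent block (MALA with the expected-information metric).**  All
   continuous latent quantities — intercepts, `log delta`, the spatial
   surface, `u`, `eta` — form one vector and take a Metropolis-adjusted
   Langevin step.  The proposal is preconditioned with the full expected
   information `F = C' diag(mu) C + prior precision`, where `C` is the
   Jacobian of the cell log-rates with respect to the latent vector; `F`
   is rebuilt every 100 warmup iterations and frozen afterwards (any fixed
   metric leaves the target invariant).  The dense metric matters: the
   intercepts, age-gender effects and the surface are strongly correlated
   a posteriori, and with a diagonal preconditioner the intercepts mix an
   order of magnitude more slowly.  Step size adapts to a 0.57 acceptance
   rate during warmup.
2. **Constraints by parameterisation, not projection.**  The surface is
   sampled in the eigenbasis of `R` restricted off its null space
   (`kappa = A z`, with `A'R A = diag(lambda)`), so each gender column sums
   to zero per connected component *exactly* at every draw and the ICAR
   quadratic form is diagonal in `z`.  Likewise `eta` lives in the
   orthogonal complement of the constant vector.  This is exact and avoids
   the subtle bias of re-centring after a Metropolis update.  Note the
   public `log_prior` reads `eta` as a full iid normal (its documented
   contract); the sampler's internal density uses the (2J-1)-dimensional
   constrained measure, which is what makes the `tau_eta` conditional
   correct.
3. **Precisions by slice sampling.**  Given the latent field, each
   log-precision has a one-dimensional full conditional
   `0.5*n_eff*log tau - 0.5*tau*S + log p(tau) + log tau` (with `n_eff` the
   constrained dimension and `S` the relevant sum of squares); a
   stepping-out slice sampler handles every hyperprior family without
   tuning.  The domain is clipped to `|log tau| <= 30`, never binding once
   data inform the field.
4. **Group moves for two soft ridges.**  (a) `delta -> delta*e^eps` with
   `kappa -> kappa*e^-eps` (disease 1's field is invariant along this
   direction, so only the sparse disease and the priors resist); includes
   the log-Jacobian `-eps * dim(z)`.  (b) `alpha_d + c` with `u_d - c`
   (likelihood-invariant; the priors decide).  Both scales adapt to a 0.44
   acceptance rate during warmup.  These directions are posterior ridges a
   position-independent metric cannot remove.

Initialisation: intercepts at the log crude rate, random effects jittered
from their `tau = 10` prior (an exactly zero field would make the precision
conditionals improper), `delta = 1`.  Chains are seeded as
`default_rng([seed, chain])`, so a fit is bitwise reproducible given its
seed.  Rank-normalised split-R-hat and bulk ESS (via ArviZ, chains split in
half) are attached to every fit, with a warning when any R-hat exceeds
1.05.

Degenerate inputs: cells with `n = 0` and `O = 0` are treated as
unobserved and contribute nothing; `O > 0` with `n = 0` is rejected at
validation.  Graphs with isolated areas are rejected by `fit` unless
`allow_islands=True` (each singleton then becomes its own constrained
block with `kappa = 0`).  Non-finite log-posterior at initialisation is
rejected with a message.  Overflowing proposals are rejected rather than
clipped.

Single-disease ("no sharing") fits reuse the same machinery: mask the other
disease's cells (`n = 0`) and pin `delta` with `fix_delta=1.0`, which
removes it from the sampled vector; the remaining model is a standard
CAR-plus-iid univariate smoother.

## Model comparison

DIC uses the plug-in deviance at the posterior mean of each cell's linear
predictor (the latent-Gaussian convention), not at posterior means of raw
parameters.  WAIC is computed pointwise (`lppd - pWAIC`, variance form with
`ddof = 1`).  The logarithmic score is the negative mean log CPO with the
harmonic-mean CPO estimator, draws pooled across chains; cells whose CPO
underflows 1e-300 are floored with a warning, since the harmonic mean is
unstable on extreme cells.

## Synthetic registry generator

`synthetic` emulates the structure of a two-disease national registry over
a five-year window: 47 areas (a packaged continental-Spain contiguity
fixture reconstructed from public adjacency; a rook grid and connected
random graphs are available for tests), 2 genders, 5 age groups.
Generating values: `delta = 1.2`, `tau_kappa = 2`, `tau_u = 4`,
`tau_eta = 1`, base rates `5e-4` (abundant) and `5e-5` (sparse) — chosen so
simulated totals land near 1e5 and 1e4 deaths and the sparse disease's
cells sit in the small-domain regime (median expected count below 10 for a
typical truth draw, expected-count ratio between the diseases within
5–15x).  Populations are person-years with a steeply decreasing age
profile (585k, 500k, 350k, 175k, 25k per average area-gender cell) and
log-normal area sizes (log-sd 1, mean-one multipliers: a few large areas,
many small ones).  Truths are drawn from the model's own priors (ICAR
draw for `kappa` via the spectral factorisation, iid normals for `u` and
centred `eta`), so recovery tests are internally consistent.

What the generator does *not* emulate: real province populations,
secular trends, age-profile regularity in `eta` (it is exchangeable, not
smooth), overdispersion beyond Poisson, or registry artefacts
(late registration, cause-of-death miscoding).  Passing recovery tests
therefore demonstrates correctness of the inference machinery under the
model's own assumptions, not robustness to their violation.

## Problem sizes used in tests and the acceptance script

Replicate studies run at the full registry scale (47 areas, ~1e5 + ~1e4
deaths) with single chains of 500–700 retained draws after equal warmup —
enough for stable 95% intervals given the sampler's effective sample sizes
(typically >100 for the slowest scalar, near-iid for precisions).  The
dev-scale test fixture is a 3x3 grid with populations divided by 50.

## Known limitations

* Exactly two diseases; no space-time terms or covariates (out of scope).
* The harmonic-mean CPO estimator can be noisy for extreme cells even with
  flooring; WAIC is the more stable criterion here.
* MALA with a frozen metric can mix slowly if the posterior's curvature
  changes strongly across its support; for Poisson counts at registry
  scale the Gaussian approximation behind the metric is excellent, but at
  very low counts (tiny populations) effective sample sizes drop and more
  iterations are needed.
* DIC's plug-in convention makes its absolute value implementation-
  dependent; comparisons are meaningful within one convention only.
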