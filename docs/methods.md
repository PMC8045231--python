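# Methods

## Composition indices

A composition is a species × fatty-acid matrix of molar percentages with a
closure invariant: each row sums to 100 within a tolerance of ±0.5 mol%
(published species means need not close exactly; an explicit
`renormalize()` rescales rows to close exactly and is never applied
implicitly). Indices:

* **class sums** — SFA (0 double bonds), MUFA (1), PUFA (≥ 2) mol% sums, and
  the n-3 PUFA / total PUFA ratio stored as a fraction in [0, 1], the scale
  the beta model needs; species with zero total PUFA get a missing ratio
  with a warning.
* **ACL** — Σ (mol fraction × chain length), in carbons.
* **DBI** — Σ (mol% × double bonds), double bonds per 100 acids.
* **PI** — Σ (mol% × c(bonds)) with c = 0.025, 1, 2, 4, 6, 8 for mono-
  through hexaenoic acids. The coefficients are an empirical peroxidation
  susceptibility scale and are not extrapolated: an acid with more than six
  double bonds raises an error.
* **AI** — 100 × (20:3n-6 + 20:5n-3 + 22:6n-3) / 20:4n-6. The numerator is a
  closed enumeration; other acids contribute nothing. Zero arachidonic acid
  gives a missing value with a warning.

Indices are computed on the proportions as given (not renormalized): when
rows close only approximately, renormalizing before ACL/DBI would silently
change published values, so the choice is left to the caller.

## Phylogenetic covariance

Under Brownian motion on a rooted tree with time-like branch lengths, the
trait covariance of two tips is the depth of their most recent common
ancestor. `vcv` accumulates this clade by clade (every non-root edge adds
its length to its clade's covariance block; a stem edge, when present, is
shared by all tips), which makes pruning exact: the covariance of an induced
subtree is the corresponding submatrix of the full matrix.

Models use the normalized (unit-diagonal) form, dividing each entry by the
geometric mean of the two diagonals; for an ultrametric tree this is
division by tree height. Normalization makes the phylogenetic standard
deviation `sigma_p` identifiable on a common scale across trees; the raw
matrix remains available for sensitivity work. Non-ultrametric trees are
accepted with a warning (per-tip diagonals are used). Matrices are factored
with an automatic 1e-8 jitter retry; a matrix that is still not positive
definite raises.

## Migration distance

Great-circle (haversine) distance on a sphere of radius 6371 km (the mean
Earth radius; configurable — the spherical-vs-ellipsoidal choice matters at
the ~0.3% level) from a configurable origin (default: Jutland centroid,
56.0° N 9.3° E) to each species' non-breeding centroid, reported in
thousands of km. Sedentary species are exactly 0 by definition, not by
computation.

## The regression model

For species *i* with design row *x_i* (intercept + z-standardized,
optionally log-transformed predictors):

* beta family: y_i ~ Beta(μ_i φ, (1 − μ_i) φ), logit μ_i = x_i′β + u_i —
  the mean–precision parameterization, variance μ(1 − μ)/(1 + φ);
* Gaussian family: y_i ~ N(x_i′β + u_i, σ_e²), response z-standardized
  (log-transformed first for AI);
* u ~ MVN(0, σ_p² C) with C the normalized Brownian correlation matrix.

Beta responses on the mol% scale are divided by 100; exact boundary values
(possible for rare acids) are pulled inside the open interval by
y′ = (y(n − 1) + 0.5)/n, applied to the whole vector only when a boundary
value occurs, and logged. Proportions are modelled on the (0, 1) scale —
required by the beta density — and average marginal effects are reported on
that scale.

Priors (all configurable): improper flat on β; half-Student-t(3, 0, 2.5) on
σ_p and σ_e; Gamma(0.01, 0.01) on φ. These mirror the weakly-informative
defaults of standard Bayesian mixed-model software, so the posterior is
dominated by the data at the sample sizes involved.

## Sampler

Adaptive Metropolis-within-Gibbs, with the species effects sampled
explicitly (no closed-form marginalization exists for the beta family).
Blocks per iteration:

1. **β** — exact conjugate Gibbs in the Gaussian family (flat prior);
   coordinate-wise random-walk Metropolis plus a joint step with proposal
   covariance ∝ (X′X)⁻¹ in the beta family (the joint step keeps mixing
   efficient when predictors are correlated, e.g. log mass and log life
   span).
2. **u, site-wise** — exact joint Gibbs draw in the Gaussian family (the
   full conditional is MVN with precision C⁻¹/σ_p² + I/σ_e²); per-site
   random-walk Metropolis with individually adapted scales in the beta
   family (two sweeps; each site touches one observation).
3. **u, whitened sweep** (beta family) — updates in the coordinates
   w = L⁻¹u/σ_p (L the Cholesky factor of C), whose prior is iid standard
   normal. Each whitened coordinate moves a correlated block of species
   coherently; without it, the common level of a tight sister clade — whose
   effects the prior almost equates — mixes far too slowly for the 1.01
   convergence threshold.
4. **translation moves** — proposals (β_j, u) → (β_j + d, u − d X_j) (and a
   joint (X′X)⁻¹-shaped variant) that leave the likelihood invariant and are
   accepted on the prior ratio alone, decoupling fixed effects from the
   species-effect mean they trade off against.
5. **σ_p** — a centered log-scale step (informed by the MVN prior of u)
   interleaved with a non-centered step that rescales u and σ_p jointly
   (ancillarity–sufficiency interweaving); the pair removes the funnel-like
   coupling that makes either parameterization alone mix slowly.
6. **φ / σ_e** — log-scale random walk (Gamma prior + Jacobian for φ;
   half-t + Jacobian for σ_e).

Proposal scales adapt by Robbins–Monro toward 0.44 acceptance during
burn-in only, so the post-burn-in kernel is a fixed Markov kernel in
detailed balance. Chains start from overdispersed points with seeds derived
deterministically from one master seed (identical seeds give identical
draws). The kernel is numba-compiled; a full 106-species fit at the default
geometry takes a few seconds on one core.

**Chain geometry.** Default: 4 chains × 4,000 iterations, 1,000 burn-in,
thinning 2 (6,000 retained draws). The published analysis's geometry
(25 × 6,000, 2,000 burn-in, thinning 10) is available as `PUBLISHED_MCMC`.
Retained draws are exactly chains × (iterations − burn-in)/thinning; the
settings validator requires divisibility.

**Diagnostics.** Classic (non-split) Gelman–Rubin R-hat,
sqrt(((n−1)/n W + B/n)/W), computed for every parameter including each u_i;
degenerate 0/0 chains return exactly 1. A fit with max R-hat > 1.01 is
flagged non-converged (returned, never raised). Equal-tailed credible
intervals use linearly interpolated empirical quantiles (the numpy
`linear` convention, documented so a sort-based oracle matches exactly).

**Average marginal effects.** Per draw, AME_j = (1/n) Σ_i ∂μ_i/∂x_ij:
β_j for the Gaussian family, β_j · mean(μ_i(1 − μ_i)) for the beta family
with μ_i evaluated at that draw's β and u (species effects are part of each
species' fitted mean; a switch averages at u = 0 instead, which in practice
shifts AMEs by a few percent). Significance = the equal-tailed 95% interval
excludes zero.

## PGLS residual correlations

β̂ = (X′C⁻¹X)⁻¹X′C⁻¹y via Cholesky whitening (a condition number above 1e12
raises rather than silently pseudo-inverting). Each variable is transformed
(logit for proportions after fraction conversion and boundary squeeze, log
for AI), regressed on an intercept and log body mass, and the Pearson
correlations of the residual vectors are reported on pairwise-complete
species. Brownian C is used as-is — no Pagel's λ or OU transformation — and
Pearson (not rank) correlation is used since the variables are
pre-transformed toward normality.

## Synthetic data

The generator emulates the statistical structure the models assume, with
defaults defining the reference study conditions:

* **Tree** — pure-birth (Yule) tree conditioned on n = 106 extant tips, the
  post-speciation waiting time drawn from its exponential law so no pendant
  edge is zero, rescaled to unit height.
* **Focal proportions** — exact beta responses: logit mean linear in
  standardized covariates (planted effect 0.3 per sd) plus a Brownian
  effect with σ_p = 0.5, precision φ = 50. These values give a realistic
  single-acid dispersion (sd ≈ 2–4 mol% for a mid-abundance acid) and an
  effect detectable but not overwhelming at n = 106 (power ≈ 0.9).
* **Compositions** — Dirichlet rows (total concentration 100) whose
  log-concentrations carry per-acid Brownian shifts (sd 0.4), preserving
  closure while giving every acid phylogenetic signal. The base profile is
  proportional to the observed median avian liver profile (C16:0 23.3,
  C18:0 22.2, C18:1n9 21.1, C18:2n6 9.3, C20:4n6 8.5, C22:6n3 3.5, C16:1n7
  1.3 mol%, minor acids ~1). A planted acid is regenerated as an exact beta
  response and the remaining acids rescaled to keep closure.
* **Life history** — log body mass ~ N(3.9, 1.2²) (≈ 50 g median); log BMR,
  log life span, log fecundity linear in log mass (slopes 0.66, 0.2, −0.15)
  plus Brownian and independent noise; recoveries log-normal positive
  counts; migratory status Bernoulli(0.6) with African/Iberian non-breeding
  centroids.

One master seed derives all component seeds via `SeedSequence`, so a dataset
is a pure function of its configuration. Ground truth for every generated
relationship is stored alongside the data.

**What the generator does not emulate** — and hence what passing tests do
not certify about real data: measurement error in gas-chromatography
proportions, within-species variation collapsed into species means,
recovery-effort bias structure beyond a positive count covariate, diet- and
tissue-driven lipid-class differences, non-Brownian trait evolution
(selection, rate shifts), and real consensus-tree uncertainty. Calibration
results (coverage, false-positive rate, power) are properties of the model
under its own generative assumptions.

## Analysis pipeline

Four fixed-effect families per response — body mass alone; life span
controlling for mass, recoveries and migration distance; fecundity with mass
and migration distance; BMR with mass — crossed with all responses: each
panel acid, SFA, MUFA, PUFA, n-3/total PUFA (beta family) and ACL, DBI, PI,
log AI (Gaussian). Life span is log-transformed like the other positive
covariates. Species missing a covariate are dropped per model, not
globally, to maximize each model's n; counts are reported. Failed or
non-converged fits become flagged rows, never batch aborts. No
multiple-testing adjustment is applied — matching the deliberately informal
stance of reporting credible intervals model by model — but the expected
number of chance significances is reported for context.

## Problem sizes in the test suite

The suite runs the full reference fit (n = 106, 4 × 4,000) once for the
convergence contract and once for parameter recovery; frequentist
calibration uses 50 replicates at a reduced geometry (2 × 1,500, burn-in
500) chosen to keep per-replicate Monte-Carlo error well below the widths
being tested; oracle comparisons use n = 120–500 with no or identity
phylogeny. Covariance properties are checked on 200 simulated trees and
MRCA-oracle equality on trees of 3–12 tips.

## Known limitations

* The beta family models each proportion separately; the compositional
  coupling between acids (closure) is represented in the generator but not
  in the likelihood, exactly as in the published analysis design.
* No model comparison (WAIC/LOO), measurement-error terms, or multivariate
  responses.
* Consensus-tree construction from posterior tree samples is out of scope; a
  single Newick tree is the contract.
* The Gelman–Rubin statistic is the classic non-split form; split-chain or
  rank-normalized variants would be stricter for short chains.
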