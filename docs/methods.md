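# Methods

## The estimation problem

Radiomics pipelines summarize a tumor image as hundreds of quantitative
features. Treating those features as direct causes of a clinical outcome is
not biologically coherent: they are *measurements* of an underlying tumor
state. `latentpls` therefore models the tumor construct as a latent
treatment `Z`, measured by the feature block `U = (U₁, …, U_K)` and
confounded by clinical covariates `X`, with the outcome `Y` depending on
`X` only through `Z`.

Identification rests on four assumptions:

1. **Ignorability** — treatment is independent of the potential outcomes
   given the confounders.
2. **Local independence** — the features are mutually independent given
   `Z` (they measure the same construct with independent errors).
3. **Measurement invariance** — the features are conditionally independent
   of other variables given `Z` (they measure the *same* construct across
   subgroups).
4. **Existence of `E(Z | X)`** — a generalized-propensity-type conditional
   mean is well defined.

Under these, `Z` d-separates both `U` and `Y` from `X`, so the outcome
regression needs only the inferred latent treatment, not the confounders.
This is load-bearing twice over: it licenses stage 2 below, and it is also
forced algebraically — the inferred treatment lies exactly in the column
space of `X`, so a regression on both would be singular.

## Two-stage estimator

**Stage 1 — kernel multivariate PLS.** With `X` (n × p) and `U` (n × K)
column-standardized (mean 0, sd 1, n−1 denominator), components are
extracted from the cross-product `A = X′U` alone. Per component *b*:
`q_b` is the dominant unit eigenvector of `A_b′A_b`; `w_b = A_b q_b`
rescaled to unit norm; the rotation `r_b = w_b − Σ_{a<b}(p_a′w_b) r_a`
maps *undeflated* `X` to scores `t_b = X r_b`; loadings
`p_b = X′t_b/(t_b′t_b)` and `q_b′ = r_b′A_b/(t_b′t_b)`; then
`A_{b+1} = A_b − p_b q_b′ (t_b′t_b)`. Coefficients are `B = R Q′`. Only
`X′U` is deflated; `X′X` never is. An equivalent cross-product-only path
(`t_b′t_b = r_b′(X′X)r_b`, `p_b = (X′X)r_b/(t_b′t_b)`) never forms the
score vectors and returns identical coefficients — the "kernel" property.
The fit reproduces classical NIPALS PLS2 component by component and
collapses to the least-squares solution at the full number of components;
both facts are asserted in the test suite against an independent NIPALS
implementation and scikit-learn.

Eigenvectors are computed by full symmetric eigendecomposition of the
(small, after cross-products) matrix rather than power iteration —
deterministic and accurate at trivial cost. Signs are fixed by orienting
each `w_b` so its largest-magnitude entry is positive (first such entry on
ties); rotations, scores and loadings inherit the orientation. A
(near-)degenerate top eigenvalue is logged, since the returned vector is
then canonical only under the tie-break.

**Stage 2 — outcome regression with bootstrap.** The inferred latent
treatment is the first-component score `t₁ = X r₁` centered and rescaled
to unit variance, so the LCE — the OLS slope of the working response on it
— reads as *effect per SD of the inferred treatment*. The percentile
bootstrap resamples subjects with replacement and re-runs the whole
pipeline per replicate (re-standardization, outcome preparation including
the Nelson–Aalen hazard, PLS, regression). Because the latent direction is
identified only up to sign, each replicate's estimate is multiplied by
`sign(r₁⁽ᵇ⁾ · r₁)` before quantiles are taken. Replicates that degenerate
(e.g. a resample with a constant confounder column) are skipped; more than
20% failures is an error. The categorical-to-dummy encoding map is built
once on the full sample and reused in replicates, so coefficients remain
comparable across resamples.

Defaults: one component (a scalar latent construct; multi-component fits
report one slope per component without pooling), B = 1000 bootstrap
replicates, 95% percentile intervals. Intervals are reported for B ≥ 50
and warned about below that.

## Outcome preparation

* Continuous outcomes pass through.
* Binary outcomes map to 0/1 against a declared positive label
  (linear-probability working response; effects are risk differences).
  More than two observed levels is an error — unordered categorical
  outcomes are out of scope.
* Survival outcomes become null-model martingale residuals
  `M_i = δ_i − Λ̂(t_i)` with `Λ̂` the Nelson–Aalen estimator
  `Λ̂(t) = Σ_{t_j ≤ t} d_j/n_j`. Censored observations tied with an event
  time stay in the risk set at that time; under this convention
  `Σ M_i = 0` exactly, which the tests assert to 1e-12. Residuals lie in
  (−∞, 1]. The residuals are not re-centered or rescaled.

## Data preparation conventions

Complete-case analysis only: tables are intersected on subject id and any
row with a missing feature, encoded confounder, or outcome value is
dropped (with a logged report). Standardization uses the n−1 denominator;
zero-variance feature columns are dropped with a warning (high-dimensional
feature blocks routinely contain constants) while a zero-variance
confounder column is an error (a constant confounder is a user mistake).
Standardization happens after complete-case filtering — the only order
that keeps means exactly zero on the analysis sample. Categorical
covariates encode as L−1 dummies against the lexicographically first
level; binary covariates as one 0/1 column; both recorded in an encoding
map for reproducibility.

## Continuum regression

The Stone–Brooks family maximizes
`Cov(y, Xβ)² · Var(Xβ)^(α/(1−α) − 1)` over unit `β`; α = 0, ½, 1 give the
OLS, first-PLS-weight and first-principal-component directions. Off the
anchors the maximizer lies on the ridge family
`β(δ) ∝ (X′X − δI)⁻¹X′y` evaluated in the eigenbasis of `X′X`; a bounded
scalar search over a transformed `δ` covers the OLS→PLS arc (δ ≤ 0) for
α < ½ and the PLS→PCR arc (δ > λ_max) for α > ½. A variance-first variant
of the objective (swapping the roles of the two factors) is exposed for
inspection but does not reproduce the anchor correspondence and is not
used for direction finding.

## Synthetic-data generator

The generator draws from the structural model the estimator assumes:
`X ~ N(0, Σ_x)`; `Z = Xγ + σ_z ε`; `U_k = g_k(a_k Z) + noise_k` with
per-feature monotone links (`identity`, `cube`, `scaled-logistic`) and
independent noise (local independence holds by construction); outcomes
`y = θZ + Xd + ε_y` (continuous), `Bernoulli(logistic(θZ + Xd))` (binary),
or exponential survival with rate `exp(θZ + Xd)` and independent uniform
censoring whose upper bound is solved numerically for a target censoring
fraction. With the direct `X→Y` term `d = 0` (the default), `Y ⊥ X | Z`
holds exactly, so the d-separation premise is literally true in simulated
data; setting `d ≠ 0` probes violations. A binarized-confounder option
mimics categorical clinical covariates and probes the multivariate-normal
design assumption.

**Default regime and why.** Defaults are n = 500, p = 3, K = 50, identity
links, unit loadings, unit feature noise, `σ_z = 1`, `θ = 1`,
`γ = (10, 10, 10)`. The γ magnitude is the one genuinely free choice and
it is deliberate: the estimator's inferred treatment is the X-predictable
part of `Z`, so its estimand is `θ·sd(Xγ)` while the natural oracle is
`θ·sd(Z)`. These coincide only when `E(Z|X)` dominates the latent noise;
the default gives a latent R² of `γ′Σγ/(γ′Σγ + σ_z²) ≈ 0.997`, under
which per-SD effects on the inferred and true latent agree to ≈ 0.03 and
latent-score correlation exceeds 0.99. With weakly informative
confounders the estimator still consistently recovers the *direction* `γ`
and the effect per SD of the inferred treatment, but that quantity is
attenuated relative to the per-SD-of-true-`Z` effect — a property of the
estimand, not an estimation error. Recovery experiments therefore report
bias against a per-replicate oracle (the realized slope of the working
response on standardized `Z`), which removes simulation noise in `Z` from
bias summaries.

**Coverage target.** Bootstrap coverage is assessed against the fixed
population value `θ·sqrt(γ′Σγ + σ_z²)`. The per-replicate realized oracle
is computed from the same draw as the estimate and is therefore
near-deterministically inside any honest interval; it is not a valid
coverage target. Measured coverage of 95% percentile intervals at n = 300,
B = 200 is ≈ 0.92 — the mild undercoverage expected of percentile
intervals for a scale-like functional at this sample size.

**What the generator does not emulate.** Real radiomics features are
heavy-tailed, blockwise highly correlated beyond what a single latent
induces, and often redundant by construction (filtered variants of the
same base feature); confounders are few and categorical rather than
Gaussian; true outcome models are not single-index. Passing recovery and
coverage tests here validates the estimation machinery under its own
assumptions — it does not certify performance on real cohorts where local
independence or measurement invariance fail.

## Problem sizes used in validation

Monte-Carlo validation uses 200 replicates for recovery (n = 500) and
coverage (n = 300, B = 200), 20 replicates per sample size for the
consistency sweep (n = 50, 200, 800), and 100 replicates for null
calibration — sizes at which the Monte-Carlo error of each summary is an
order of magnitude smaller than the property being checked.

## Numerical choices and degenerate inputs

* Component count must satisfy `1 ≤ l ≤ rank(X)`; a numerically zero
  deflated cross-product (`‖A_b‖ < 1e-12`) raises "no remaining
  covariance".
* Deflation exhausts the cross-product after `rank(X)` components (the
  deflated `X′U` equals `X_residual′U`, and the scores span col(X) by
  then); the tests assert a relative Frobenius residual below 1e-8.
* A constant working response yields slope exactly 0 and a degenerate
  (0, 0) interval rather than an error.
* Bootstrap indices, simulation draws and sub-seeds all flow from a single
  integer seed through `numpy.random.default_rng`; no global RNG state is
  touched, and equal seeds give bitwise-identical results.
* The NIPALS reference implementation (tests only) iterates to 1e-12 with
  a 500-iteration default cap; its convergence is linear in the spectral
  gap, so validation against near-degenerate spectra raises the cap rather
  than the tolerance.

## Known limitations

* Effect homogeneity over `Z` is assumed; the reported LCE is a pooled
  slope, and effect modification is out of scope.
* No selection rule for the number of components is provided; the default
  of one matches a scalar latent construct.
* The latent scale is indeterminate, so estimates are only comparable
  across datasets through the per-SD convention; they are not comparable
  to fits using other score normalizations or score sides. The U-side
  scores of the bilinear PLS model are not currently exposed as the
  treatment; the X-side scores are the quantity the kernel algorithm
  computes and the two-step strategy calls for.
* Complete-case filtering assumes missingness unrelated to the latent
  construct; no imputation is offered.
* The PC1 baseline and the PLS estimator can disagree in sign: PC1 is
  oriented by the feature covariance alone while the PLS scores are
  oriented by the confounder cross-product, and neither orientation is
  canonical. Both fits are surfaced so the comparison is explicit.
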