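# Methods

## Setting and assumptions

The package targets longitudinal observational studies with `n`
independent patients enrolled at baseline (visit 0) and followed at visits
`1..T`.  The data model assumes, per patient and visit: treatment `A_ij`
(binary; ordinal, coded by nested indicators `A0` "any treatment" and `A1`
"highest level"; or continuous), a time-varying covariate vector `X_ij`,
baseline covariates `V_i`, outcome `Y_ij`, and an in-study indicator
`R_ij` with `R_i0 = 1` and monotone dropout (`R_{i,j-1}=0 ⇒ R_ij=0`).
Temporal ordering within a visit is treatment → covariates → outcome, and
each variable may depend only on the observed past.  Identification rests
on sequential ignorability of treatment and of censoring given observed
history, positivity for both processes, SUTVA, and a correctly specified
MSM.  Violations of these assumptions are not detectable by the package's
diagnostics and can bias all estimators it produces.

Intermittent (non-monotone) missingness is rejected at load time, not
imputed: preprocessing is the caller's responsibility.

## Weights and calibration restrictions

Initial weights are stabilized inverse-probability-of-treatment weights
times unstabilized inverse-probability-of-censoring weights, built from
pooled-over-visits MLE fits (visit indicators may be included as model
terms; per-visit fits can be emulated by interacting every term with visit
indicators).  The ordinal treatment model is the continuation-ratio
factorization into two logistic stages, the continuous model a
heteroscedastic normal with log-linear variance, censoring a pooled
logistic model for retention among those at risk.

Calibration restrictions are linear in the calibrated weights `W★`:

* *Treatment blocks*: row `(i,j)`, column `c` holds the cumulative score
  `Σ_{k≤j} (A_ik − ê_ik) X̃_{i,k-1,c}`, with `ê` predicted from the
  treatment-history-only (numerator) fit and `X̃` the full-model terms;
  targets are zero.  Ordinal treatments contribute one column set per
  stage (stage-2 sums run over visits with `A0=1`); continuous treatments
  contribute standardized-residual mean columns and variance columns.
* *Censoring block*: row `(i,j)`, column `c` holds
  `(T−j+1) H̃_{i,j−1,c} − (T−j) H̃_{ij,c}` with target `T Σ_i H̃_{i0,c}`.
  This is the telescoped (per-row) form of requiring, at every visit, zero
  weighted covariate imbalance between consecutive uncensored samples; it
  is equivalent to the visit-by-visit balance sums, an identity the test
  suite verifies directly against the un-telescoped double sum.
* *Normalization block* (only for treatment-only Type 1 calibration): the
  mean calibrated weight is 1 at each visit, which rules out the trivial
  all-zero solution.  It is redundant — and therefore rejected — when the
  censoring block is present, since that block already pins the weighted
  sample size.

H̃ terms use the same vocabulary as model terms (constant, baseline
covariates, lagged time-varying covariates, visit indicators and
products), evaluated relative to the risk visit, so visit-specific balance
of any covariate can be requested by adding `visit==k` interactions.

A deliberate reading choice: for continuous treatments the restriction
rows are weighted by the person-period's own in-study indicator `R_ij`
(matching the binary/ordinal pattern), not by completer status at the
final visit; restricting to completers would discard information and
break the telescoping structure.

## Solvers

**Type 1 (exponential tilting).**  `W★(λ) = W ∘ exp(Kλ)` turns the moment
conditions into the gradient of the strictly convex objective
`1ᵀ{W ∘ exp(Kλ)} − lᵀλ`, minimized by damped Newton: exact Hessian
`Kᵀ diag(W★) K`, Armijo backtracking (c₁ = 1e-4, halving), a
gradient-descent fallback if the Newton direction fails, λ initialized at
0, iteration cap 200.  Convergence is declared when the gradient max-norm
(equal to the restriction residual) falls below 1e-8 absolute; if line
search stalls earlier from floating-point limits, a residual below
`1e-6 · max(1, ‖l‖∞)` is still accepted.  Exponents are clipped at ±40
only inside line-search trials, never at the reported solution.
Infeasible targets (no positive-weight solution; objective unbounded
below) are detected when the tilt exponent exceeds 200 in magnitude and
reported with the direction of unboundedness.  Newton's affine invariance
makes column standardization unnecessary for the iterates; it is exposed
as an `assemble_system(standardize=True)` option for linear-solve
conditioning, with the weight solution invariant (tested).

**Type 2 (estimating equations).**  `W★ = W(α̂, β, θ)` keeps the standard
weight form and re-solves for the denominator/censoring parameters by
`scipy.optimize.root` (Powell hybrid), starting at the MLE plus random
perturbations (default 3 starts, scale 0.25·(1+|MLE|)).  The parameter
count must equal the number of restrictions, which is automatic when the
restriction terms equal the model terms and normalization rows are
omitted.  Non-convergence and multiple solutions (converged weight
vectors differing beyond proportionality, max-norm 1e-6 after
normalization) are reported via flags — both are expected, documented
behaviors of this route rather than bugs; the multi-start protocol is a
package choice, as is treating flags rather than exceptions as the
reporting channel.

**Diagnostics.**  The variance of the calibration factor `exp(k_iᵀλ̂)`
across person-periods is the model-checking statistic: it converges to
zero under correctly specified initial weights and stays bounded away
from zero under misspecification (verified by simulation in the test
suite).  Per-column pre/post balance, per-visit effective sample sizes
`(Σw)²/Σw²` and the maximum weight are also reported.

## MSM estimation

The identity-link MSM with unit working variance and independence working
correlation reduces the weighted estimating equations to weighted least
squares over uncensored person-period rows, solved exactly by linear
algebra; the solution is invariant to rescaling all weights.  The working
variance is a package choice — it keeps the estimator a WLS and is the
standard choice for IPW-MSMs; non-identity links and non-independence
working correlations are out of scope for this version.  Standard errors
come from a nonparametric bootstrap resampling patients with replacement
and re-running the entire pipeline (model fits → restrictions →
calibration → MSM) per replicate; replicates whose calibration fails are
dropped and counted.

Optional weight rescaling mirrors common practice for avoiding extreme
weights: treatment-only weights can be scaled to sum to the number of
observations, product weights to `T × n`.  Fitted probabilities are
clipped to `[1e-8, 1−1e-8]` before weight computation (clip events are
counted); an exact zero/negative fitted probability raises a positivity
error naming the person-period.

## Synthetic-data generator

The generator emulates the target application — an HIV-cohort-like study
with an ordinal 3-level treatment, covariate-driven assignment, monotone
covariate-dependent dropout and a continuous longitudinal outcome — while
remaining fully specified and reproducible.  Defaults (all overridable):

| parameter | default | meaning |
|---|---|---|
| `n`, `T` | 500, 3 | patients, follow-up visits |
| `a_prev`, `a_x`, `a_v` | 0.6, 0.5, 0.4 | treatment logits: previous level, confounder, baseline |
| `a_intercepts` | (0, −0.5) | ordinal stage intercepts |
| `rho`, `kappa`, `sd_x` | 0, 0.8, 1 | confounder autoregression, response to treatment, noise |
| `theta0`, `theta_a`, `theta_x`, `sd_y` | 0, 1, 0.5, 1 | outcome law |
| `psi` | (2, −0.4, 0.3) | retention logits (≈25% dropout by T=3, ≈45% by T=5) |

With `rho = 0` the implied MSM is exactly
`E(Y_j^ā) = θ0 + θ_a Σ_{l≤j} a_l + θ_x κ a_j`, giving closed-form true
coefficients `(θ_a, θ_x κ)` for the cumulative/current design.  Because
the confounder–outcome laws are linear-Gaussian, potential-outcome means
have an exact closed form for any `rho` (`potential_outcome_means`), so
no Monte-Carlo truth is needed; for `rho > 0` the cumulative/current MSM
is no longer saturated in the generating mean and coefficient "truth" is
not defined, so `true_msm_parameters` refuses rather than projecting.

`misspecification="transform"` exports `exp(X/2)` in place of `X`
(Kang–Schafer-style functional-form misspecification); the generating
process is unchanged, so analysis models linear in the exported covariate
are misspecified while the truth is known.

What the generator does *not* emulate: intermittent missingness,
measurement error, non-Gaussian outcomes, treatment effect heterogeneity
beyond the specified design, calendar-time structure, and the
high-dimensional covariate sets of real cohorts.  Passing tests therefore
demonstrate correctness of the estimator's mechanics and its claimed
finite-sample balance/efficiency properties under these stylized
conditions, not robustness on any particular real data set.

Randomness: one root seed; normals and uniforms are drawn from two
separate child streams in patient-major blocks, so growing `n` appends
patients without changing earlier ones, and per-replicate seeds are
derived from the study seed.  The "true weights" reference estimator uses
unstabilized true inverse-probability weights recorded by the generator
(the true marginal treatment-history numerator has no closed form, and
any treatment-history-only numerator — including 1 — leaves the weighted
estimator consistent).

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run the Monte-Carlo checks at
n ∈ {500, 2000, 8000} (50–100 replicates) for the calibration-function
shrinkage, 200 replicates at n = 1000 for bias under correct
specification, and 200 replicates at n = 500 for the misspecification MSE
comparison — sizes chosen so the whole suite completes in a few minutes
on one CPU while keeping Monte-Carlo error well below the effect sizes
being asserted.

## Known limitations

* Identity link only; eventual-outcome (end-of-study) restriction
  variants and stabilized-censoring-weight calibration are not
  implemented.
* Exact balance only: approximate (inequality-tolerance) balance, which
  would allow many more restrictions, is out of scope.
* No analytic (sandwich) variances; bootstrap only.
* Constrained-optimization ("Type 3") weight estimation is deliberately
  not offered: without the model structure of Types 1–2 it need not
  converge to the true inverse-probability weights in longitudinal
  settings.
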