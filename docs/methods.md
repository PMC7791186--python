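# Methods

## Model family

The package models a growth z-score `X_t` (weight-for-length against a
growth standard; age `t` in months as a continuous real) as a narrow-sense
linear SDE

    dX_t = (p(t) + a1·X_t) dt + s·dW_t,    p(t) = a2 + a3·t + a4·t² + a5·t³,

with drift polynomial order 0–3, optional mean reversion `a1`, and constant
diffusion `s > 0`. `W_t` is a Wiener process. The Ornstein–Uhlenbeck (OU)
process `dX = α(β − X)dt + σ dW` is the reparameterization
`a1 = −α, a2 = αβ, s = σ` at drift order 0.

For this family the Fokker–Planck equation has a Gaussian solution, so the
transition (slice) density of `X_{t1}` given `(x0, t0)` is

    mean     m = e^{a1 Δ} x0 + ∫_{t0}^{t1} e^{a1 (t1−u)} p(u) du,   Δ = t1 − t0,
    variance v = s² (e^{2 a1 Δ} − 1) / (2 a1),

with the continuous `a1 → 0` limits `m = x0 + ∫p`, `v = s²Δ`. Rather than
transcribing the (long) printed closed form of the cubic-drift transition
mean, the implementation evaluates the drift integral through the helper
integrals `φ_j(a, Δ) = ∫_0^Δ e^{av} v^j dv` (j ≤ 3), computed by a
truncated power series for `|aΔ| < 0.75` and the integration-by-parts
recurrence otherwise. This gives uniform ~1e−14 relative accuracy across
the whole parameter range, including the removable singularity at
`a1 = 0`; the test suite verifies agreement with adaptive quadrature, with
an independently transcribed literal form of the cubic-drift mean, with
the OU closed form, and with Euler–Maruyama Monte Carlo.

Site (study location) enters as additive offsets on drift parameters and
as an additive offset on `log s`. The log scale for the diffusion is a
convention, not an identity taken from any data set: it is the simplest
link that keeps `s > 0` for every site.

## Likelihood

A child's trajectory `X_0 … X_{N−1}` contributes the product of slice
densities over consecutive visits; the first observation is conditioned on
(treated as a constant) and contributes no term, as is standard in
transition-based SDE estimation and in time-series practice. Children are
independent given their parameters. Because the slice density is exact for
any elapsed time, visits at irregular ages and gaps from missed visits
enter the likelihood directly.

## Estimation

**Fixed effects** (`fit_mle`): bounded L-BFGS-B on transformed parameters
(`log s`; in the OU parameterization also `log α`, keeping α > 0, while in
the natural parameterization `a1` is unconstrained in sign). Starting
values come from a quadratic-variation estimate of `s` and a least-squares
regression of per-visit velocity `Δx/Δt` on the drift basis, with the
level `x0` demeaned within child so that between-child heterogeneity does
not bias the reversion-speed start. Five restarts by default (jittered
starts, seeded); the best optimum is kept.

**Mixed effects** (`fit_mixed_sde`): child-level random effects `b_i ~
N(0, Σ_b)` on any subset of parameters; effects on `s` (and on `α` in the
OU parameterization) act on the log scale, effects on drift parameters are
additive. The marginal likelihood integrates each child's likelihood over
`b_i` by **adaptive Gauss–Hermite quadrature**: per child the posterior
mode is found by vectorized Newton iteration (exactly concave when the
random effect enters the transition mean), nodes are recentred at the mode
and rescaled by the curvature; 5 nodes per dimension by default, tensor
product up to two dimensions, Laplace approximation above that. `Σ_b` is
parameterized by its Cholesky factor with log diagonal (diagonal or
unstructured), so the estimate is positive semi-definite by construction.
Setting `re_cov_fixed=0` degenerates exactly to the fixed-effects fit.
Empirical-Bayes modes `b̂_i` are reported per child and drive prediction.
The outer optimization starts both from the fixed-effects optimum and from
the regression heuristic: on strongly clustered cohorts the former can sit
in a basin where between-child spread is absorbed into a near-zero
reversion speed, and the second start escapes it.

**Standard errors**: Wald, from a central-finite-difference Hessian of the
negative log-likelihood at the optimum (step 1e−4 relative), delta method
for log-scale parameters. p-values for trimming are two-sided Wald tests.

**Baselines** (`fit_linear_baseline`): the naive transition model
`X1|X0 ~ N(X0 + b·Δt, σ²)` (2 parameters, closed-form MLE) and the global
linear regression `X(t) ~ N(c0 + c1·t, σ²)` (3 parameters, OLS).

**LMM comparator** (`fit_lmm`): response polynomial in age (order ≤ 4)
with optional site main effect and age-by-site interactions; random
effects on a subset of age terms with unstructured (or diagonal)
covariance; within-child errors independent or AR(1) *in visit order*
(`ρ^{|j−k|}`), the standard discrete serial-correlation structure for
scheduled visits. The Gaussian marginal likelihood uses the closed
per-child covariance `Z_i Σ_b Z_iᵀ + σ²R_i(ρ)`; fixed effects are profiled
by GLS and the variance parameters maximized numerically (`atanh ρ`,
`log σ`, Cholesky-log `Σ_b`). This is implemented in-package because the
available mixed-model library does not support AR(1) residuals; the
independent-error special case is cross-checked against it in the tests.

**Information criteria**: `AIC = 2k − 2·logL`, `BIC = k·log(n) − 2·logL`,
`k` counting fixed effects plus variance/covariance parameters (including
ρ), `n` the total number of observation rows for every model class, so SDE
and LMM fits are compared on identical data. Counting rows rather than
transitions is a convention, stated here so comparisons are internally
consistent.

**Model search** (`model_search`): enumerates drift orders (≤ 3) and LMM
polynomial orders (≤ 4), candidate random-effect sets and covariance
structures; after each fit the highest-p fixed term is dropped while its
p-value exceeds 0.1; all successful fits are returned ranked by AIC.

## Synthetic cohorts

`simulate_cohort` emulates the structure of an intensive two-site birth
cohort: a monthly schedule of 25 visits over 0–24 months; visit-age jitter
from a truncated normal (sd 5 days, hard cap ±14 days, converted to months
by /30.4375, never below age 0); per-visit Bernoulli missingness (default
2.8%, first visit never dropped, putting ~85% of children at ≥ 24 visits —
the completeness level such studies report); child-level random effects
drawn once per child; the initial value from a configurable per-site
Gaussian (the SDE models transitions, so the anchor must be supplied).
Trajectories are generated by *exact* transition sampling, not
discretization.

Deliberately not emulated: informative missingness (drop-out correlated
with growth), measurement error, seasonality, covariates beyond site, and
cross-child dependence. Passing tests therefore demonstrate correctness of
the estimators under the model's own assumptions and realistic visit
structure — not robustness to misspecification in field data.

## Prediction

From a grid of (age, z-score) starting points, forecasts to 24 months use
the per-child parameter sets of a mixed fit (fixed effects + empirical-
Bayes effects). At each step the sets are ranked by **locality**: the
slice-density value each set assigns to the current point, for a process
started at that child's own first observed visit (children whose first
visit is later than the current age are excluded; a child whose anchor
coincides exactly with the point ranks first via a +inf sentinel, ties
broken by cohort order). The most local set steps the state forward by the
slice mean over a small age increment (default 0.1 months), and the
selection is re-evaluated at the new point, so the chosen set may switch
along a path. Ten sensitivity paths repeat the walk within 10 seeded
random groups of children. Design choices made where the procedure was
genuinely open: the forward step uses the slice *mean* (the most likely
path, matching the deterministic look of stream plots) rather than a
random draw; locality is the single-slice density from each child's first
visit rather than a product along a visited path; both are stated here as
package conventions.

## Numerical and reproducibility notes

* Series/recurrence switch for `φ_j` at `|aΔ| = 0.75`; 30 series terms
  (machine precision for that radius).
* Optimizer bounds keep `log`-parameters in [−12, 6] and drift
  coefficients in [−60, 60] to avoid overflow during line search;
  non-finite objective values are mapped to a large constant.
* Quadrature default of 5 nodes/dimension is exact (to ~1e−11) when the
  random effect enters the transition mean, since the integrand is then
  Gaussian; for log-scale effects the 5-vs-21-node difference is at the
  1e−4-per-child level on realistic fits.
* All randomness flows from explicit seeds (cohort design, fit restarts,
  fold assignment); pipeline artifacts carry a config-hash + seed
  provenance line and contain no timestamps, so a fixed configuration is
  byte-reproducible. Cohort CSVs are written with shortest round-trip
  float formatting and read back with round-trip parsing, making
  write → read lossless.
* Problem sizes in the test suite and acceptance script (e.g. 20
  replicates of 200 children × 25 visits for fixed-effect recovery; 100
  children for mixed recovery; 120 children for the two-cluster stream
  study; 10⁵ Euler–Maruyama paths at step 10⁻³ for density verification)
  were chosen as the smallest designs at which the corresponding
  statistical checks have comfortable power.

## Known limitations

* Only drifts linear in `X` with constant diffusion have closed-form
  Gaussian slices; state-dependent diffusion or nonlinear drift would
  require numerical transition densities and is out of scope.
* Wald standard errors and p-values rely on the usual asymptotics; no
  profile-likelihood or bootstrap intervals.
* The Laplace fallback (> 2 random-effect dimensions) is less accurate
  than quadrature; random effects on `log s`/`log α` make `sd(·)`
  estimates log-normal-scale quantities.
* The prediction procedure is deliberately simple — argmax locality with
  mean stepping — and carries no formal predictive intervals; the 10-fold
  paths indicate robustness, not coverage.
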