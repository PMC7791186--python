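# growthsde

Drift-and-diffusion modelling of childhood growth trajectories with
stochastic differential equations (SDEs).

Longitudinal anthropometry — here weight-for-length z-scores (ZWfL) over
ages 0–24 months — is dominated by large within- and between-child
variability that defeats simple curve fitting. `growthsde` models each
child's trajectory as a continuous-time stochastic process

```
dX_t = (p(t) + a1·X_t) dt + s·dW_t ,       p(t) = a2 + a3·t + a4·t² + a5·t³
```

where the **drift** `p(t) + a1·X_t` captures slow developmental trends
(with optional mean reversion through `a1`) and the **diffusion** `s·dW_t`
captures short-term shocks such as illness or infection. The
Ornstein–Uhlenbeck (OU) process `dX = α(β − X)dt + σ dW` is the special
case `a1 = −α, a2 = αβ`, with reversion speed `α` and long-term mean `β`.

Because the drift is linear in `X` and the diffusion constant, the
transition ("slice") density between any two ages is exactly Gaussian with
closed-form mean and variance, so fitting reduces to ordinary maximum
likelihood over observed transitions — irregular and missing visits are
handled natively, with no imputation. The package provides:

* **`growthsde.models`** — the linear-SDE family, exact slice densities,
  the OU covariance function, YAML (de)serialization.
* **`growthsde.simulate`** — exact trajectory simulation, an
  Euler–Maruyama oracle, and a synthetic-cohort generator emulating a
  two-site birth cohort (monthly visits with ±14-day jitter, missed
  visits, child-level random effects, site effects).
* **`growthsde.fit`** — transition-likelihood MLE, mixed-effects fits with
  child-level random effects (adaptive Gauss–Hermite quadrature), linear
  baselines, Wald standard errors, AIC/BIC.
* **`growthsde.lmm`** — the classical comparator: polynomial-age linear
  mixed models with AR(1) within-child errors.
* **`growthsde.search`** — AIC/BIC-guided model search with p-value
  trimming (drop terms with p > 0.1).
* **`growthsde.predict`** — grid-based prediction of future trajectories
  using per-child empirical-Bayes parameter sets ranked by slice-density
  "locality", with 10-fold sensitivity paths. On cohorts with latent
  subgroups the forecasts collapse into a small number of "streams".
* **`growthsde.cli`** — `growthsde simulate | fit | predict | summarize | run`.

## Worked example

```python
from growthsde import (CohortDesign, FitOptions, fit_linear_baseline,
                       fit_mle, ou_model, simulate_cohort)

model = ou_model(alpha=1.2, beta=-0.8, sigma=0.6)
design = CohortDesign(n_children_per_site=100, sites=("haydom", "venda"),
                      seed=1, initial_mean=-0.8, initial_sd=0.4)
cohort = simulate_cohort(model, design)
print(f"{len(cohort)} children, {sum(len(t) for t in cohort)} visits")

fit = fit_mle(ou_model(1.0, 0.0, 1.0), cohort,
              options=FitOptions(n_restarts=2, seed=0), parameterization="ou")
for name in ("alpha", "beta", "sigma"):
    print(f"{name:>6}: {fit.estimates[name]: .4f}  (SE {fit.standard_errors[name]:.4f})")
print(f"log-likelihood {fit.loglik:.1f}, AIC {fit.aic:.1f}, BIC {fit.bic:.1f}")

lr = fit_linear_baseline(cohort, kind="global")
print(f"linear regression AIC {lr.aic:.1f}  (OU improves by {lr.aic - fit.aic:.1f})")
```

prints

```
200 children, 4869 visits
 alpha:  1.3132  (SE 0.0523)
  beta: -0.8158  (SE 0.0074)
 sigma:  0.6183  (SE 0.0116)
log-likelihood -1913.6, AIC 3833.2, BIC 3852.7
linear regression AIC 4442.8  (OU improves by 609.6)
```

The cohort was generated with `α = 1.2, β = −0.8, σ = 0.6`; all three
estimates land within about two standard errors of the generating values,
and the OU transition model dominates a 3-parameter global linear
regression by ~600 AIC points on the same data — mean reversion plus
elapsed-time-dependent variance is a far better description of growth
dynamics than a straight line through all visits.

## Documentation

See `docs/methods.md` for the model, estimation details (quadrature,
optimizer, standard errors), what the synthetic cohorts do and do not
emulate, and known limitations.
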