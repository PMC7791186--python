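"""Maximum-likelihood fitting of linear-SDE growth models.

The likelihood of a trajectory is the product of Gaussian slice densities
over consecutive observed visits; the first observation is conditioned on
(treated as a constant), so an N-visit child contributes N-1 transition
terms.  Because the slice density handles any elapsed time exactly,
irregular and missing visits need no imputation.

Three fitting routes are provided:

* ``fit_mle`` — fixed-effects fits of any family member, by bounded
  quasi-Newton on transformed parameters (diffusion and OU reversion speed
  on the log scale) with multi-start.
* ``fit_mixed_sde`` — child-level random effects on named parameters,
  marginalized by adaptive Gauss–Hermite quadrature (tensor nodes up to two
  random-effect dimensions, Laplace above that).  Random effects on the
  diffusion and on the OU speed act on the log scale, keeping both positive.
* ``fit_linear_baseline`` — the two reference models: the naive linear
  transition model X1|X0 ~ N(X0 + b*(t1-t0), sigma^2) and the global linear
  regression ZWfL(t) ~ N(c0 + c1*t, sigma^2).

Standard errors are Wald, from a central-finite-difference Hessian of the
negative log-likelihood at the optimum (delta method for log-scale
parameters).  AIC = 2k - 2logL and BIC = k*log(n) - 2logL with n the total
number of observation rows.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp
from scipy.stats import norm

from .models import PARAM_NAMES, SDEModelSpec, ou_model, slice_mean_var
from .simulate import Trajectory

__all__ = [
    "FitOptions",
    "FitResult",
    "CohortData",
    "trajectory_negloglik",
    "cohort_negloglik",
    "fit_mle",
    "fit_linear_baseline",
    "fit_mixed_sde",
    "materialize_child_models",
]

_BIG = 1e10  # objective value returned on numerical failure
_DRIFT_NAMES = ("a1", "a2", "a3", "a4", "a5")


# ----------------------------------------------------------------------
# cohort container
# ----------------------------------------------------------------------
class CohortData:
    """Flat transition arrays for vectorized likelihood evaluation."""

    def __init__(self, trajectories: Sequence[Trajectory]):
        trajectories = list(trajectories)
        if not trajectories:
            raise ValueError("cohort is empty")
        for tr in trajectories:
            if len(tr) < 2:
                raise ValueError(
                    f"trajectory {tr.child_id!r} has fewer than 2 points"
                )
        self.trajectories = trajectories
        self.child_ids = [tr.child_id for tr in trajectories]
        self.child_site = [tr.site for tr in trajectories]
        sites = sorted({tr.site for tr in trajectories}, key=lambda s: (s is None, s))
        self.sites = sites
        site_pos = {s: i for i, s in enumerate(sites)}

        t0, t1, x0, x1, cidx, sidx = [], [], [], [], [], []
        for ci, tr in enumerate(trajectories):
            a, v = tr.ages, tr.values
            t0.append(a[:-1]); t1.append(a[1:])
            x0.append(v[:-1]); x1.append(v[1:])
            m = len(a) - 1
            cidx.append(np.full(m, ci, dtype=np.intp))
            sidx.append(np.full(m, site_pos[tr.site], dtype=np.intp))
        self.t0 = np.concatenate(t0)
        self.t1 = np.concatenate(t1)
        self.x0 = np.concatenate(x0)
        self.x1 = np.concatenate(x1)
        self.child_idx = np.concatenate(cidx)
        self.site_idx = np.concatenate(sidx)
        self.n_children = len(trajectories)
        self.n_transitions = len(self.t0)
        self.n_obs = self.n_transitions + self.n_children  # total rows

    @classmethod
    def ensure(cls, cohort) -> "CohortData":
        return cohort if isinstance(cohort, cls) else cls(cohort)


# ----------------------------------------------------------------------
# likelihood kernels
# ----------------------------------------------------------------------
def _transition_nll_terms(a1, b, s, t0, t1, x0, x1):
    """Per-transition negative log slice density; may contain inf."""
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        mean, var = slice_mean_var(a1, b, s, t0, t1, x0)
        r = x1 - mean
        out = 0.5 * (np.log(2.0 * math.pi * var) + r * r / var)
    return out


def trajectory_negloglik(
    model: SDEModelSpec,
    trajectory: Trajectory,
    params: Mapping[str, float] | None = None,
    site=None,
) -> float:
    """Negative log-likelihood of one trajectory under the model.

    The first observation is conditioned on and contributes no term.
    ``params`` optionally overrides the model's parameter values (after site
    offsets are applied); this is how per-child parameter sets are scored.
    """
    if len(trajectory) < 2:
        raise ValueError("trajectory needs at least 2 points for a likelihood")
    site = trajectory.site if site is None else site
    p = model.params_for_site(site)
    if params:
        p.update(params)
    a = trajectory.ages
    v = trajectory.values
    if np.any(np.diff(a) <= 0):
        raise ValueError("trajectory ages must be strictly increasing")
    b = (p["a2"], p["a3"], p["a4"], p["a5"])
    if p["s"] == 0.0:
        mean, _ = slice_mean_var(p["a1"], b, 1.0, a[:-1], a[1:], v[:-1])
        if np.allclose(v[1:], mean, rtol=0, atol=1e-12):
            return 0.0
        warnings.warn(
            "zero-variance transition with mismatched value: likelihood is 0",
            RuntimeWarning,
        )
        return math.inf
    terms = _transition_nll_terms(p["a1"], b, p["s"], a[:-1], a[1:], v[:-1], v[1:])
    return float(np.sum(terms))


def cohort_negloglik(model, trajectories, params=None) -> float:
    """Sum of per-child trajectory negative log-likelihoods."""
    return float(
        sum(trajectory_negloglik(model, tr, params=params) for tr in trajectories)
    )


# ----------------------------------------------------------------------
# parameter families (free-vector <-> natural parameters)
# ----------------------------------------------------------------------
class _Family:
    """Maps an optimizer vector (transformed scale) to per-transition
    natural parameters, and back to reportable estimates."""

    names: list
    transforms: list  # 'id' or 'log' per name

    def natural_estimates(self, theta):
        out = {}
        for name, tr, z in zip(self.names, self.transforms, theta):
            out[name] = math.exp(z) if tr == "log" else float(z)
        return out

    def natural_se(self, theta, se_z):
        out = {}
        for name, tr, z, se in zip(self.names, self.transforms, theta, se_z):
            out[name] = math.exp(z) * se if tr == "log" else float(se)
        return out

    def bounds(self):
        return [
            (-12.0, 6.0) if tr == "log" else (-60.0, 60.0)
            for tr in self.transforms
        ]


class NaturalFamily(_Family):
    """Free parameters are the drift coefficients present in the template,
    the log diffusion, and (optionally) per-site additive offsets for the
    parameters named in the template's ``site_offsets``; the first site in
    sorted order is the reference (offset 0)."""

    def __init__(self, template: SDEModelSpec, sites: Sequence):
        self.template = template
        self.sites = list(sites)
        self.drift_names = [n for n in _DRIFT_NAMES if n in template.params]
        self.names = list(self.drift_names) + ["s"]
        self.transforms = ["id"] * len(self.drift_names) + ["log"]
        self.offset_keys = []  # (param_name, site)
        for pname in sorted(template.site_offsets):
            for site in self.sites[1:]:
                self.offset_keys.append((pname, site))
                self.names.append(f"{pname}@{site}")
                self.transforms.append("id")
        self.trimmable = [n for n in self.drift_names]
        self.re_scale = {n: "id" for n in self.drift_names}
        self.re_scale["s"] = "log"

    def theta0(self, cohort: CohortData):
        dt = cohort.t1 - cohort.t0
        dx = cohort.x1 - cohort.x0
        s0 = math.sqrt(max(np.mean(dx * dx / dt), 1e-4))
        counts = np.bincount(cohort.child_idx, minlength=cohort.n_children)
        child_mean = (
            np.bincount(cohort.child_idx, weights=cohort.x0, minlength=cohort.n_children)
            / np.maximum(counts, 1)
        )
        cols = []
        for n in self.drift_names:
            if n == "a1":
                # demeaned within child: robust to between-child level shifts
                cols.append(cohort.x0 - child_mean[cohort.child_idx])
            else:
                k = _DRIFT_NAMES.index(n) - 1
                cols.append(cohort.t0**k)
        if cols:
            A = np.column_stack(cols)
            coef, *_ = np.linalg.lstsq(A, dx / dt, rcond=None)
        else:
            coef = np.zeros(0)
        theta = list(np.clip(coef, -20, 20)) + [math.log(s0)]
        theta += [0.0] * len(self.offset_keys)
        return np.array(theta)

    def _split(self, theta):
        k = len(self.drift_names)
        base = {n: theta[i] for i, n in enumerate(self.drift_names)}
        log_s = theta[k]
        offsets = {
            key: theta[k + 1 + i] for i, key in enumerate(self.offset_keys)
        }
        return base, log_s, offsets

    def transition_params(self, theta, cohort: CohortData, re_names=(), b=None):
        base, log_s, offsets = self._split(theta)
        n_sites = len(self.sites)
        shape = cohort.site_idx
        vals = {}
        for n in _DRIFT_NAMES:
            v = np.full(n_sites, base.get(n, 0.0))
            for i, site in enumerate(self.sites):
                v[i] += offsets.get((n, site), 0.0)
            vals[n] = v[shape]
        ls = np.full(n_sites, log_s)
        for i, site in enumerate(self.sites):
            ls[i] += offsets.get(("s", site), 0.0)
        log_s_tr = ls[shape]
        if b is not None:
            for j, rn in enumerate(re_names):
                bc = b[:, j][cohort.child_idx]
                if rn == "s":
                    log_s_tr = log_s_tr + bc
                else:
                    vals[rn] = vals[rn] + bc
        s = np.exp(np.clip(log_s_tr, -40, 40))
        return vals["a1"], (vals["a2"], vals["a3"], vals["a4"], vals["a5"]), s

    def model_from(self, theta) -> SDEModelSpec:
        est = self.natural_estimates(theta)
        params = {n: est[n] for n in self.drift_names}
        params["s"] = est["s"]
        site_offsets: dict = {}
        for pname, site in self.offset_keys:
            site_offsets.setdefault(pname, {s: 0.0 for s in self.sites})
            site_offsets[pname][site] = est[f"{pname}@{site}"]
        order = max(
            (_DRIFT_NAMES.index(n) - 1 for n in self.drift_names if n != "a1"),
            default=0,
        )
        return SDEModelSpec(
            drift_order=max(order, 0),
            mean_reversion="a1" in self.drift_names,
            params=params,
            site_offsets=site_offsets,
        )

    def child_model(self, theta, re_values: Mapping[str, float]) -> SDEModelSpec:
        base = self.model_from(theta)
        params = dict(base.params)
        for name, bval in re_values.items():
            if name == "s":
                params["s"] = math.exp(math.log(params["s"]) + bval)
            else:
                params[name] = params.get(name, 0.0) + bval
        return SDEModelSpec(
            drift_order=base.drift_order,
            mean_reversion=base.mean_reversion,
            params=params,
            site_offsets=base.site_offsets,
        )


class OUFamily(_Family):
    """OU convenience parameterization (alpha, beta, sigma); the reversion
    speed alpha and diffusion sigma are fitted on the log scale, so random
    effects on them are log-normal while the long-term mean beta is plain
    additive."""

    def __init__(self, template: SDEModelSpec, sites: Sequence):
        if template.site_offsets:
            raise ValueError(
                "site offsets are only supported in the natural parameterization"
            )
        if not template.is_ou:
            raise ValueError("OU parameterization requires an OU-form template")
        self.template = template
        self.sites = list(sites)
        self.names = ["alpha", "beta", "sigma"]
        self.transforms = ["log", "id", "log"]
        self.trimmable = []
        self.re_scale = {"alpha": "log", "beta": "id", "sigma": "log"}

    def theta0(self, cohort: CohortData):
        dt = cohort.t1 - cohort.t0
        dx = cohort.x1 - cohort.x0
        s0 = math.sqrt(max(np.mean(dx * dx / dt), 1e-4))
        # within-child demeaned regression of velocity on level: robust to
        # between-child heterogeneity in the long-term mean
        counts = np.bincount(cohort.child_idx, minlength=cohort.n_children)
        child_mean = (
            np.bincount(cohort.child_idx, weights=cohort.x0, minlength=cohort.n_children)
            / np.maximum(counts, 1)
        )
        xc = cohort.x0 - child_mean[cohort.child_idx]
        denom = float(np.sum(xc * xc))
        a1_hat = float(np.sum(xc * dx / dt) / denom) if denom > 1e-12 else -1.0
        alpha0 = float(np.clip(-a1_hat, 0.05, 20.0))
        beta0 = float(np.clip(np.mean(cohort.x0), -10.0, 10.0))
        return np.array([math.log(alpha0), beta0, math.log(s0)])

    def transition_params(self, theta, cohort: CohortData, re_names=(), b=None):
        la = np.full(cohort.n_children, theta[0])
        be = np.full(cohort.n_children, theta[1])
        ls = np.full(cohort.n_children, theta[2])
        if b is not None:
            for j, rn in enumerate(re_names):
                if rn == "alpha":
                    la = la + b[:, j]
                elif rn == "beta":
                    be = be + b[:, j]
                elif rn == "sigma":
                    ls = ls + b[:, j]
        alpha = np.exp(np.clip(la, -30, 30))[cohort.child_idx]
        beta = be[cohort.child_idx]
        s = np.exp(np.clip(ls, -40, 40))[cohort.child_idx]
        zero = np.zeros_like(alpha)
        return -alpha, (alpha * beta, zero, zero, zero), s

    def model_from(self, theta) -> SDEModelSpec:
        est = self.natural_estimates(theta)
        return ou_model(est["alpha"], est["beta"], est["sigma"])

    def child_model(self, theta, re_values: Mapping[str, float]) -> SDEModelSpec:
        est = self.natural_estimates(theta)
        alpha = est["alpha"] * math.exp(re_values.get("alpha", 0.0))
        beta = est["beta"] + re_values.get("beta", 0.0)
        sigma = est["sigma"] * math.exp(re_values.get("sigma", 0.0))
        return ou_model(alpha, beta, sigma)


def _make_family(template, cohort, parameterization):
    if parameterization == "auto":
        parameterization = "ou" if (template.is_ou and not template.site_offsets) else "natural"
    if parameterization == "ou":
        return OUFamily(template, cohort.sites)
    if parameterization == "natural":
        return NaturalFamily(template, cohort.sites)
    raise ValueError(f"unknown parameterization {parameterization!r}")


# ----------------------------------------------------------------------
# results
# ----------------------------------------------------------------------
@dataclass
class FitResult:
    """Estimates and goodness-of-fit of one fitted model."""

    estimates: dict
    standard_errors: dict
    loglik: float
    n_params: int
    n_obs: int
    aic: float
    bic: float
    converged: bool
    label: str = ""
    message: str = ""
    random_effects_cov_hat: np.ndarray | None = None
    re_names: tuple = ()
    empirical_bayes: dict | None = None
    parameterization: str = "natural"
    model: SDEModelSpec | None = None
    extra: dict = field(default_factory=dict)

    @property
    def p_values(self) -> dict:
        """Two-sided Wald p-values, est/se against zero."""
        out = {}
        for name, est in self.estimates.items():
            se = self.standard_errors.get(name)
            if se and np.isfinite(se) and se > 0:
                out[name] = 2.0 * float(norm.sf(abs(est / se)))
            else:
                out[name] = float("nan")
        return out

    def to_dict(self) -> dict:
        d = {
            "label": self.label,
            "estimates": {k: float(v) for k, v in self.estimates.items()},
            "standard_errors": {
                k: float(v) for k, v in self.standard_errors.items()
            },
            "loglik": float(self.loglik),
            "n_params": int(self.n_params),
            "n_obs": int(self.n_obs),
            "aic": float(self.aic),
            "bic": float(self.bic),
            "converged": bool(self.converged),
            "message": self.message,
            "parameterization": self.parameterization,
            "re_names": list(self.re_names),
        }
        if self.random_effects_cov_hat is not None:
            d["random_effects_cov_hat"] = np.asarray(
                self.random_effects_cov_hat
            ).tolist()
        if self.empirical_bayes is not None:
            d["empirical_bayes"] = {
                cid: {k: float(v) for k, v in eb.items()}
                for cid, eb in self.empirical_bayes.items()
            }
        if self.model is not None:
            d["model"] = self.model.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "FitResult":
        return cls(
            estimates=dict(d["estimates"]),
            standard_errors=dict(d["standard_errors"]),
            loglik=d["loglik"],
            n_params=d["n_params"],
            n_obs=d["n_obs"],
            aic=d["aic"],
            bic=d["bic"],
            converged=d["converged"],
            label=d.get("label", ""),
            message=d.get("message", ""),
            random_effects_cov_hat=(
                np.asarray(d["random_effects_cov_hat"])
                if "random_effects_cov_hat" in d
                else None
            ),
            re_names=tuple(d.get("re_names", ())),
            empirical_bayes=d.get("empirical_bayes"),
            parameterization=d.get("parameterization", "natural"),
            model=(
                SDEModelSpec.from_dict(d["model"]) if d.get("model") else None
            ),
        )


def _information_criteria(loglik, n_params, n_obs):
    aic = 2.0 * n_params - 2.0 * loglik
    bic = n_params * math.log(n_obs) - 2.0 * loglik
    return aic, bic


@dataclass
class FitOptions:
    """Optimizer controls shared by the fitting routines."""

    n_restarts: int = 5
    seed: int = 0
    maxiter: int = 1000
    gtol: float = 1e-8
    jitter_sd: float = 0.3
    agh_nodes: int = 5
    inner_maxiter: int = 40
    hessian_step: float = 1e-4


def _fd_hessian(f, x, rel_step=1e-4):
    """Central-difference Hessian of scalar f at x."""
    x = np.asarray(x, float)
    n = len(x)
    h = rel_step * (1.0 + np.abs(x))
    H = np.empty((n, n))
    f0 = f(x)
    for i in range(n):
        ei = np.zeros(n); ei[i] = h[i]
        fpp = f(x + ei); fmm = f(x - ei)
        H[i, i] = (fpp - 2.0 * f0 + fmm) / h[i] ** 2
        for j in range(i + 1, n):
            ej = np.zeros(n); ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return H


def _wald_se(f, theta, rel_step):
    H = _fd_hessian(f, theta, rel_step)
    try:
        cov = np.linalg.pinv(H)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(len(theta), np.nan)
    return se


def _multistart(objective, theta0, bounds, options: FitOptions):
    """L-BFGS-B from one or more starting points plus jittered restarts."""
    rng = np.random.default_rng(options.seed)
    best = None
    inits = theta0 if isinstance(theta0, list) else [theta0]
    starts = [np.asarray(t, float) for t in inits]
    for _ in range(max(options.n_restarts - 1, 0)):
        base = starts[0]
        starts.append(base + options.jitter_sd * rng.standard_normal(len(base)))
    for start in starts:
        start = np.clip(start, [b[0] for b in bounds], [b[1] for b in bounds])
        res = minimize(
            objective,
            start,
            method="L-BFGS-B",
            bounds=bounds,
            options={
                "maxiter": options.maxiter,
                "gtol": options.gtol,
                "ftol": 1e-12,
            },
        )
        if best is None or res.fun < best.fun:
            best = res
    return best


# ----------------------------------------------------------------------
# fixed-effects MLE
# ----------------------------------------------------------------------
def fit_mle(
    model_template: SDEModelSpec,
    cohort,
    options: FitOptions | None = None,
    parameterization: str = "auto",
    label: str = "",
) -> FitResult:
    """Fixed-effects maximum likelihood over the summed transition
    likelihood of all trajectories."""
    options = options or FitOptions()
    data = CohortData.ensure(cohort)
    fam = _make_family(model_template, data, parameterization)

    def objective(theta):
        a1, b, s = fam.transition_params(theta, data)
        terms = _transition_nll_terms(a1, b, s, data.t0, data.t1, data.x0, data.x1)
        val = float(np.sum(terms))
        return val if np.isfinite(val) else _BIG

    res = _multistart(objective, fam.theta0(data), fam.bounds(), options)
    theta = res.x
    converged = bool(res.success) and res.fun < _BIG
    se_z = _wald_se(objective, theta, options.hessian_step)
    estimates = fam.natural_estimates(theta)
    ses = fam.natural_se(theta, se_z)
    loglik = -float(res.fun)
    k = len(fam.names)
    aic, bic = _information_criteria(loglik, k, data.n_obs)
    return FitResult(
        estimates=estimates,
        standard_errors=ses,
        loglik=loglik,
        n_params=k,
        n_obs=data.n_obs,
        aic=aic,
        bic=bic,
        converged=converged,
        label=label or f"sde[{'/'.join(fam.names)}]",
        message=str(res.message),
        parameterization=(
            "ou" if isinstance(fam, OUFamily) else "natural"
        ),
        model=fam.model_from(theta),
        extra={"theta": theta.tolist()},
    )


# ----------------------------------------------------------------------
# linear baselines
# ----------------------------------------------------------------------
def fit_linear_baseline(cohort, kind: str = "transition") -> FitResult:
    """Reference linear models.

    kind='transition': X1|X0 ~ N(X0 + b*(t1-t0), sigma^2) — 2 parameters,
    likelihood over the same transitions as the SDE fits.
    kind='global': ordinary linear regression of z-score on age — 3
    parameters, likelihood over every observation row.
    """
    data = CohortData.ensure(cohort)
    if kind == "transition":
        dt = data.t1 - data.t0
        dx = data.x1 - data.x0
        bhat = float(np.sum(dx * dt) / np.sum(dt * dt))
        resid = dx - bhat * dt
        n = len(dx)
        sig2 = float(np.mean(resid**2))
        loglik = -0.5 * n * (math.log(2 * math.pi * sig2) + 1.0)
        estimates = {"b": bhat, "sigma": math.sqrt(sig2)}
        ses = {
            "b": math.sqrt(sig2 / float(np.sum(dt * dt))),
            "sigma": math.sqrt(sig2 / (2.0 * n)),
        }
        k = 2
        label = "linear-transition"
    elif kind == "global":
        ages = np.concatenate([tr.ages for tr in data.trajectories])
        vals = np.concatenate([tr.values for tr in data.trajectories])
        X = np.column_stack([np.ones_like(ages), ages])
        coef, *_ = np.linalg.lstsq(X, vals, rcond=None)
        resid = vals - X @ coef
        n = len(vals)
        sig2 = float(np.mean(resid**2))
        loglik = -0.5 * n * (math.log(2 * math.pi * sig2) + 1.0)
        XtX_inv = np.linalg.inv(X.T @ X)
        estimates = {"c0": float(coef[0]), "c1": float(coef[1]), "sigma": math.sqrt(sig2)}
        ses = {
            "c0": math.sqrt(sig2 * XtX_inv[0, 0]),
            "c1": math.sqrt(sig2 * XtX_inv[1, 1]),
            "sigma": math.sqrt(sig2 / (2.0 * n)),
        }
        k = 3
        label = "linear-global"
    else:
        raise ValueError("kind must be 'transition' or 'global'")
    aic, bic = _information_criteria(loglik, k, data.n_obs)
    return FitResult(
        estimates=estimates,
        standard_errors=ses,
        loglik=loglik,
        n_params=k,
        n_obs=data.n_obs,
        aic=aic,
        bic=bic,
        converged=True,
        label=label,
    )


# ----------------------------------------------------------------------
# mixed effects
# ----------------------------------------------------------------------
def _chol_from_covparams(cov_params, d, structure):
    L = np.zeros((d, d))
    if structure == "diagonal":
        L[np.diag_indices(d)] = np.exp(np.clip(cov_params, -30, 30))
    else:  # unstructured: row-major lower triangle, log diagonal
        k = 0
        for i in range(d):
            for j in range(i + 1):
                if i == j:
                    L[i, j] = math.exp(min(cov_params[k], 30))
                else:
                    L[i, j] = cov_params[k]
                k += 1
    return L


def _n_covparams(d, structure):
    return d if structure == "diagonal" else d * (d + 1) // 2


def _gh_nodes(d, n_nodes):
    z1, w1 = np.polynomial.hermite.hermgauss(n_nodes)
    if d == 1:
        return z1[:, None], np.log(w1)
    grids = np.meshgrid(*([z1] * d), indexing="ij")
    z = np.column_stack([g.ravel() for g in grids])
    logw = np.zeros(len(z))
    for i in range(d):
        logw += np.log(w1)[
            np.meshgrid(*([np.arange(n_nodes)] * d), indexing="ij")[i].ravel()
        ]
    return z, logw


class _MixedLikelihood:
    """Adaptive Gauss–Hermite marginal likelihood over child random effects.

    The per-child integrand g_i(b) = loglik_i(b) + log N(b; 0, Sigma_b) is
    maximized by vectorized Newton iteration across all children at once
    (finite-difference derivatives), then integrated with Gauss–Hermite
    nodes recentred at the mode and rescaled by the curvature (Laplace
    approximation when more than two random-effect dimensions).
    """

    def __init__(self, fam, data, re_names, structure, options):
        self.fam = fam
        self.data = data
        self.re_names = tuple(re_names)
        self.d = len(self.re_names)
        self.structure = structure
        self.options = options
        self.use_laplace = self.d > 2
        n_nodes = 1 if self.use_laplace else options.agh_nodes
        self.z_nodes, self.logw = _gh_nodes(self.d, max(n_nodes, 1))
        self.b_warm = np.zeros((data.n_children, self.d))

    def child_loglik(self, theta_fix, b):
        a1, bb, s = self.fam.transition_params(
            theta_fix, self.data, self.re_names, b
        )
        terms = _transition_nll_terms(
            a1, bb, s, self.data.t0, self.data.t1, self.data.x0, self.data.x1
        )
        terms = np.where(np.isfinite(terms), terms, _BIG)
        return -np.bincount(
            self.data.child_idx, weights=terms, minlength=self.data.n_children
        )

    def _penalized(self, theta_fix, b, Linv, logdetL):
        u = b @ Linv.T
        quad = np.sum(u * u, axis=1)
        return (
            self.child_loglik(theta_fix, b)
            - 0.5 * quad
            - logdetL
            - 0.5 * self.d * math.log(2.0 * math.pi)
        )

    def _find_modes(self, theta_fix, Linv, logdetL):
        """Vectorized Newton ascent of the penalized objective per child."""
        b = self.b_warm.copy()
        d = self.d
        h = 1e-5
        n = self.data.n_children
        g = lambda bb: self._penalized(theta_fix, bb, Linv, logdetL)
        for _ in range(self.options.inner_maxiter):
            g0 = g(b)
            grad = np.zeros((n, d))
            hess = np.zeros((n, d, d))
            gp = {}
            gm = {}
            for i in range(d):
                e = np.zeros(d); e[i] = h
                gp[i] = g(b + e); gm[i] = g(b - e)
                grad[:, i] = (gp[i] - gm[i]) / (2 * h)
                hess[:, i, i] = (gp[i] - 2 * g0 + gm[i]) / h**2
            for i in range(d):
                for j in range(i + 1, d):
                    ei = np.zeros(d); ei[i] = h
                    ej = np.zeros(d); ej[j] = h
                    hij = (
                        g(b + ei + ej) - g(b + ei - ej) - g(b - ei + ej) + g(b - ei - ej)
                    ) / (4 * h * h)
                    hess[:, i, j] = hess[:, j, i] = hij
            # Newton step with curvature guard
            if d == 1:
                hd = hess[:, 0, 0]
                neg = hd < -1e-10
                step = np.where(neg, grad[:, 0] / np.where(neg, hd, -1.0), -0.1 * grad[:, 0])[:, None]
            else:
                step = np.zeros((n, d))
                for i in range(n):
                    Hi = hess[i]
                    try:
                        w = np.linalg.eigvalsh(Hi)
                        if np.max(w) < -1e-10:
                            step[i] = np.linalg.solve(Hi, grad[i])
                        else:
                            step[i] = -grad[i] * 0.1
                    except np.linalg.LinAlgError:
                        step[i] = -grad[i] * 0.1
            b_new = b - step
            # backtracking: accept only improvements, halve otherwise
            for _bt in range(8):
                improved = g(b_new) >= g0 - 1e-12
                if improved.all():
                    break
                b_new = np.where(improved[:, None], b_new, (b + b_new) / 2.0)
            b = b_new
            if np.max(np.abs(grad)) < 1e-7:
                break
        self.b_warm = b
        return b, hess

    def marginal_negloglik(self, theta_fix, cov_params):
        L = _chol_from_covparams(cov_params, self.d, self.structure)
        return self.marginal_negloglik_L(theta_fix, L)

    def marginal_negloglik_L(self, theta_fix, L):
        try:
            Linv = np.linalg.inv(L)
        except np.linalg.LinAlgError:
            return _BIG
        logdetL = float(np.sum(np.log(np.abs(np.diag(L)))))
        b_hat, hess = self._find_modes(theta_fix, Linv, logdetL)
        n = self.data.n_children
        d = self.d
        g_at = lambda bb: self._penalized(theta_fix, bb, Linv, logdetL)
        # per-child scale matrices C_i with C_i C_i^T = (-H_i)^{-1}
        Cs = np.zeros((n, d, d))
        logdetC = np.zeros(n)
        ok = np.ones(n, dtype=bool)
        if d == 1:
            w1 = np.clip(-hess[:, 0, 0], 1e-10, None)
            Cs[:, 0, 0] = 1.0 / np.sqrt(w1)
            logdetC = -0.5 * np.log(w1)
        else:
            for i in range(n):
                A = -hess[i]
                A = 0.5 * (A + A.T)
                try:
                    w, v = np.linalg.eigh(A)
                    w = np.clip(w, 1e-10, None)
                    Ci = v @ np.diag(1.0 / np.sqrt(w)) @ v.T
                    Cs[i] = Ci
                    logdetC[i] = -0.5 * float(np.sum(np.log(w)))
                except np.linalg.LinAlgError:
                    ok[i] = False
        if self.use_laplace:
            g0 = g_at(b_hat)
            per_child = g0 + 0.5 * d * math.log(2.0 * math.pi) + logdetC
        else:
            K = len(self.z_nodes)
            vals = np.zeros((K, n))
            for k in range(K):
                zb = np.einsum("nij,j->ni", Cs, self.z_nodes[k]) * math.sqrt(2.0)
                vals[k] = (
                    g_at(b_hat + zb)
                    + np.sum(self.z_nodes[k] ** 2)
                    + self.logw[k]
                )
            per_child = logsumexp(vals, axis=0) + 0.5 * d * math.log(2.0) + logdetC
        if not np.all(np.isfinite(per_child[ok])):
            return _BIG
        total = float(np.sum(per_child))
        return -total if np.isfinite(total) else _BIG


def fit_mixed_sde(
    model_template: SDEModelSpec,
    cohort,
    re_names: Sequence[str],
    re_cov_structure: str = "diagonal",
    options: FitOptions | None = None,
    parameterization: str = "auto",
    re_cov_fixed: np.ndarray | None = None,
    label: str = "",
) -> FitResult:
    """Mixed-effects SDE fit: child-level random effects on ``re_names``.

    The marginal likelihood integrates the transition likelihood over
    b_i ~ N(0, Sigma_b) per child.  Sigma_b is parameterized through its
    Cholesky factor with log-diagonal, so the estimate is positive
    semi-definite by construction.  ``re_cov_fixed`` pins Sigma_b (an
    all-zero matrix degenerates to the fixed-effects fit).
    """
    options = options or FitOptions()
    data = CohortData.ensure(cohort)
    fam = _make_family(model_template, data, parameterization)
    re_names = tuple(re_names)
    if not re_names:
        raise ValueError("re_names must be non-empty; use fit_mle otherwise")
    for rn in re_names:
        if rn not in fam.names:
            raise ValueError(
                f"random effect {rn!r} is not a parameter of this family "
                f"({fam.names})"
            )
    if re_cov_structure not in ("diagonal", "unstructured"):
        raise ValueError("re_cov_structure must be 'diagonal' or 'unstructured'")
    d = len(re_names)

    if re_cov_fixed is not None and not np.any(np.asarray(re_cov_fixed)):
        # degenerate mixture: all children share the fixed effects
        base = fit_mle(
            model_template, data, options=options, parameterization=parameterization
        )
        base.label = label or base.label + "+re0"
        base.re_names = re_names
        base.random_effects_cov_hat = np.zeros((d, d))
        base.empirical_bayes = {
            cid: {rn: 0.0 for rn in re_names} for cid in data.child_ids
        }
        return base

    mix = _MixedLikelihood(fam, data, re_names, re_cov_structure, options)
    n_fix = len(fam.names)
    n_cov = 0 if re_cov_fixed is not None else _n_covparams(d, re_cov_structure)

    fixed_L = None
    if re_cov_fixed is not None:
        cov = np.atleast_2d(np.asarray(re_cov_fixed, float))
        w, v = np.linalg.eigh(cov)
        fixed_L = v @ np.diag(np.sqrt(np.clip(w, 1e-12, None)))

    def objective(theta):
        theta_fix = theta[:n_fix]
        if re_cov_fixed is not None:
            return mix.marginal_negloglik_L(theta_fix, fixed_L)
        return mix.marginal_negloglik(theta_fix, theta[n_fix:])

    # starting values: fixed-effect fit, random-effect sd ~ 0.3
    quick = FitOptions(
        n_restarts=max(options.n_restarts - 2, 1),
        seed=options.seed,
        maxiter=options.maxiter,
    )
    base_fit = fit_mle(model_template, data, options=quick, parameterization=parameterization)
    theta_fix0 = np.asarray(base_fit.extra["theta"])
    # between-child spread of per-child mean level: a sensible scale for
    # random effects entering the transition mean
    counts = np.bincount(data.child_idx, minlength=data.n_children)
    child_means = (
        np.bincount(data.child_idx, weights=data.x0, minlength=data.n_children)
        / np.maximum(counts, 1)
    )
    sd_between = float(np.clip(np.std(child_means), 0.1, 5.0))
    mean_like = {"beta", "a2", "a3", "a4", "a5"}

    def _sd0(rn):
        return sd_between if rn in mean_like else 0.3

    if n_cov:
        if re_cov_structure == "diagonal":
            cov0 = np.array([math.log(_sd0(rn)) for rn in re_names])
        else:
            cov0 = []
            for i in range(d):
                for j in range(i + 1):
                    cov0.append(math.log(_sd0(re_names[i])) if i == j else 0.0)
            cov0 = np.asarray(cov0)
        # two principled starts: the fixed-effects optimum, and the raw
        # regression heuristic (the former can sit in a basin where the
        # random effect is absorbed into a near-zero reversion speed)
        theta0 = [
            np.concatenate([theta_fix0, cov0]),
            np.concatenate([fam.theta0(data), cov0]),
        ]
    else:
        theta0 = [theta_fix0, fam.theta0(data)]
    bounds = fam.bounds() + [(-8.0, 3.0)] * n_cov

    res = _multistart(objective, theta0, bounds, options)
    theta = res.x
    converged = bool(res.success) and res.fun < _BIG
    loglik = -float(res.fun)
    k = n_fix + n_cov
    aic, bic = _information_criteria(loglik, k, data.n_obs)
    se_z = _wald_se(objective, theta, options.hessian_step)
    estimates = fam.natural_estimates(theta[:n_fix])
    ses = fam.natural_se(theta[:n_fix], se_z[:n_fix])
    if n_cov:
        L = _chol_from_covparams(theta[n_fix:], d, re_cov_structure)
        cov_hat = L @ L.T
        for j, rn in enumerate(re_names):
            estimates[f"sd({rn})"] = math.sqrt(cov_hat[j, j])
            # delta method on the log-sd parameter for the diagonal structure
            if re_cov_structure == "diagonal":
                ses[f"sd({rn})"] = math.sqrt(cov_hat[j, j]) * se_z[n_fix + j]
    else:
        cov_hat = np.atleast_2d(np.asarray(re_cov_fixed, float))

    # empirical-Bayes modes at the optimum
    w, v = np.linalg.eigh(cov_hat)
    L_eb = v @ np.diag(np.sqrt(np.clip(w, 1e-12, None)))
    Linv = np.linalg.inv(L_eb)
    logdetL = float(np.sum(np.log(np.abs(np.diag(L_eb)))))
    b_hat, _ = mix._find_modes(theta[:n_fix], Linv, logdetL)
    eb = {
        cid: {rn: float(b_hat[i, j]) for j, rn in enumerate(re_names)}
        for i, cid in enumerate(data.child_ids)
    }
    return FitResult(
        estimates=estimates,
        standard_errors=ses,
        loglik=loglik,
        n_params=k,
        n_obs=data.n_obs,
        aic=aic,
        bic=bic,
        converged=converged,
        label=label or f"mixed-sde[{','.join(re_names)}|{re_cov_structure}]",
        message=str(res.message),
        random_effects_cov_hat=cov_hat,
        re_names=re_names,
        empirical_bayes=eb,
        parameterization=("ou" if isinstance(fam, OUFamily) else "natural"),
        model=fam.model_from(theta[:n_fix]),
        extra={"theta": theta.tolist(), "n_fix": n_fix},
    )


def empirical_bayes_modes(fit: FitResult, cohort, options: FitOptions | None = None) -> dict:
    """Empirical-Bayes random-effect modes for a (possibly new) cohort at a
    mixed fit's estimated parameters.

    Holding the fixed effects and Sigma_b at the fitted values, the
    per-child posterior modes are recomputed on the supplied trajectories —
    e.g. to examine how shrinkage changes when children have fewer visits.
    """
    if fit.random_effects_cov_hat is None or "theta" not in fit.extra:
        raise ValueError("requires an in-session mixed-effects fit")
    options = options or FitOptions()
    data = CohortData.ensure(cohort)
    fam = _make_family(fit.model, data, fit.parameterization)
    n_fix = fit.extra.get("n_fix", len(fam.names))
    theta_fix = np.asarray(fit.extra["theta"])[:n_fix]
    mix = _MixedLikelihood(fam, data, fit.re_names, "diagonal", options)
    cov = np.atleast_2d(np.asarray(fit.random_effects_cov_hat, float))
    w, v = np.linalg.eigh(cov)
    L = v @ np.diag(np.sqrt(np.clip(w, 1e-12, None)))
    Linv = np.linalg.inv(L)
    logdetL = float(np.sum(np.log(np.abs(np.diag(L)))))
    b_hat, _ = mix._find_modes(theta_fix, Linv, logdetL)
    return {
        cid: {rn: float(b_hat[i, j]) for j, rn in enumerate(fit.re_names)}
        for i, cid in enumerate(data.child_ids)
    }


def materialize_child_models(fit: FitResult, cohort) -> dict:
    """Per-child SDE models from a mixed fit: fixed effects plus each
    child's empirical-Bayes random-effect offsets.

    Random effects on the diffusion (and on the OU reversion speed) act on
    the log scale, matching the fitted model.
    """
    if fit.empirical_bayes is None or fit.model is None:
        raise ValueError("materialize_child_models requires a mixed-effects fit")
    data = CohortData.ensure(cohort)
    out = {}
    for cid in data.child_ids:
        eb = fit.empirical_bayes.get(cid, {})
        if fit.parameterization == "ou":
            alpha, beta, sigma = fit.model.ou_params()
            out[cid] = ou_model(
                alpha * math.exp(eb.get("alpha", 0.0)),
                beta + eb.get("beta", 0.0),
                sigma * math.exp(eb.get("sigma", 0.0)),
            )
        else:
            params = dict(fit.model.params)
            for name, bval in eb.items():
                if name == "s":
                    params["s"] = math.exp(math.log(params["s"]) + bval)
                else:
                    params[name] = params.get(name, 0.0) + bval
            out[cid] = SDEModelSpec(
                drift_order=fit.model.drift_order,
                mean_reversion=fit.model.mean_reversion,
                params=params,
                site_offsets=fit.model.site_offsets,
            )
    return out
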