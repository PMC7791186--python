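"""Linear mixed models with AR(1) within-child errors — the classical
curve-fitting comparator for the SDE fits.

The response (growth z-score) is modelled as a polynomial in age with
site main effect and age-by-site interactions in the fixed part, child-level
random effects on a subset of the age terms (unstructured or diagonal
covariance), and within-child errors that are either independent or AR(1)
in visit order.  The marginal likelihood has the closed per-child form

    y_i ~ N(X_i beta, Z_i Sigma_b Z_i' + sigma^2 R_i(rho)),

with ``R_i`` the AR(1) correlation matrix ``rho^|j-k|`` over the child's
visit order.  Fixed effects are profiled out by generalized least squares at
each variance-parameter value, and the variance parameters (Cholesky of
Sigma_b with log diagonal, log sigma, atanh rho) are maximized numerically.
AIC/BIC use the same observation count as the SDE fits, so the two model
classes are directly comparable on one cohort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.linalg import qr, solve_triangular
from scipy.optimize import minimize

from .fit import (
    CohortData,
    FitOptions,
    FitResult,
    _fd_hessian,
    _information_criteria,
    _BIG,
)

__all__ = ["LMMSpec", "fit_lmm"]


@dataclass(frozen=True)
class LMMSpec:
    """Specification of the polynomial-age linear mixed model.

    Parameters
    ----------
    poly_order : int
        Order of the age polynomial in the fixed effects (<= 4).
    site_interactions : tuple of int
        Age powers whose coefficient gets a per-site offset; power 0 is the
        site main effect.
    random_terms : tuple of int
        Age powers (0 = intercept) carrying child-level random effects.
    re_cov : str
        'unstructured' or 'diagonal' random-effects covariance.
    error_cov : str
        'AR1' or 'independent' within-child errors.
    dropped_terms : tuple of str
        Fixed-effect column names removed by p-value trimming (gaps in the
        polynomial are allowed; the intercept cannot be dropped).
    """

    poly_order: int = 2
    site_interactions: tuple = ()
    random_terms: tuple = (0, 1)
    re_cov: str = "unstructured"
    error_cov: str = "AR1"
    dropped_terms: tuple = ()

    def __post_init__(self):
        object.__setattr__(self, "dropped_terms", tuple(self.dropped_terms))
        if "age^0" in self.dropped_terms:
            raise ValueError("the intercept cannot be dropped")
        if not 0 <= self.poly_order <= 4:
            raise ValueError("poly_order must be between 0 and 4")
        object.__setattr__(self, "site_interactions", tuple(self.site_interactions))
        object.__setattr__(self, "random_terms", tuple(sorted(self.random_terms)))
        if any(p > self.poly_order for p in self.random_terms):
            raise ValueError("random_terms must be within the fixed polynomial")
        if self.re_cov not in ("unstructured", "diagonal"):
            raise ValueError("re_cov must be 'unstructured' or 'diagonal'")
        if self.error_cov not in ("AR1", "independent"):
            raise ValueError("error_cov must be 'AR1' or 'independent'")


def _design(spec: LMMSpec, ages, site_idx, n_sites):
    """Fixed-effect design matrix and column names for one child."""
    cols = [np.ones_like(ages)]
    names = ["age^0"]
    for p in range(1, spec.poly_order + 1):
        cols.append(ages**p)
        names.append(f"age^{p}")
    for p in spec.site_interactions:
        for s in range(1, n_sites):
            dummy = (site_idx == s).astype(float)
            cols.append(dummy * ages**p)
            names.append(f"age^{p}:site{s}" if p else f"site{s}")
    keep = [i for i, n in enumerate(names) if n not in spec.dropped_terms]
    return np.column_stack([cols[i] for i in keep]), [names[i] for i in keep]


def _z_matrix(spec: LMMSpec, ages):
    if not spec.random_terms:
        return np.zeros((len(ages), 0))
    return np.column_stack([ages**p for p in spec.random_terms])


def fit_lmm(
    spec: LMMSpec,
    cohort,
    options: FitOptions | None = None,
    label: str = "",
) -> FitResult:
    """Maximum-likelihood fit of the polynomial LMM with AR(1) errors."""
    options = options or FitOptions()
    data = CohortData.ensure(cohort)
    n_sites = len(data.sites)
    site_pos = {s: i for i, s in enumerate(data.sites)}

    Xs, Zs, ys = [], [], []
    names = None
    for tr in data.trajectories:
        sidx = np.full(len(tr), site_pos[tr.site])
        X, names = _design(spec, tr.ages, sidx, n_sites)
        Xs.append(X)
        Zs.append(_z_matrix(spec, tr.ages))
        ys.append(tr.values)
    p_fix = Xs[0].shape[1]
    n_total = sum(len(y) for y in ys)

    # collinearity check on the stacked design
    X_all = np.vstack(Xs)
    rank = np.linalg.matrix_rank(X_all)
    if rank < p_fix:
        _, _, piv = qr(X_all, mode="economic", pivoting=True)
        bad = [names[j] for j in piv[rank:]]
        raise ValueError(f"singular fixed-effect design; collinear terms: {bad}")

    d = len(spec.random_terms)
    n_re_par = (d * (d + 1) // 2) if spec.re_cov == "unstructured" else d
    use_ar1 = spec.error_cov == "AR1"
    n_var = n_re_par + 1 + (1 if use_ar1 else 0)

    def unpack(v):
        L = np.zeros((d, d))
        k = 0
        if spec.re_cov == "unstructured":
            for i in range(d):
                for j in range(i + 1):
                    L[i, j] = math.exp(min(v[k], 30)) if i == j else v[k]
                    k += 1
        else:
            for i in range(d):
                L[i, i] = math.exp(min(v[k], 30))
                k += 1
        sigma = math.exp(min(v[k], 30)); k += 1
        rho = math.tanh(v[k]) if use_ar1 else 0.0
        return L, sigma, rho

    def profile_nll(v, want_beta=False):
        L, sigma, rho = unpack(v)
        XtVX = np.zeros((p_fix, p_fix))
        XtVy = np.zeros(p_fix)
        logdet = 0.0
        chols = []
        for X, Z, y in zip(Xs, Zs, ys):
            m = len(y)
            if use_ar1 and rho != 0.0:
                idx = np.arange(m)
                R = rho ** np.abs(idx[:, None] - idx[None, :])
            else:
                R = np.eye(m)
            V = sigma**2 * R
            if d:
                ZL = Z @ L
                V = V + ZL @ ZL.T
            try:
                c = np.linalg.cholesky(V)
            except np.linalg.LinAlgError:
                return (_BIG, None, None) if want_beta else _BIG
            logdet += 2.0 * float(np.sum(np.log(np.diag(c))))
            Xw = solve_triangular(c, X, lower=True)
            yw = solve_triangular(c, y, lower=True)
            XtVX += Xw.T @ Xw
            XtVy += Xw.T @ yw
            chols.append((c, Xw, yw))
        try:
            beta = np.linalg.solve(XtVX, XtVy)
        except np.linalg.LinAlgError:
            return (_BIG, None, None) if want_beta else _BIG
        quad = 0.0
        for (c, Xw, yw) in chols:
            r = yw - Xw @ beta
            quad += float(r @ r)
        nll = 0.5 * (logdet + quad + n_total * math.log(2.0 * math.pi))
        if not np.isfinite(nll):
            nll = _BIG
        if want_beta:
            return nll, beta, XtVX
        return nll

    # start: OLS residual scale
    beta0, *_ = np.linalg.lstsq(X_all, np.concatenate(ys), rcond=None)
    resid = np.concatenate(ys) - X_all @ beta0
    s0 = max(float(np.std(resid)), 1e-3)
    v0 = []
    if spec.re_cov == "unstructured":
        for i in range(d):
            for j in range(i + 1):
                v0.append(math.log(max(s0 * 0.5, 1e-3)) if i == j else 0.0)
    else:
        v0 += [math.log(max(s0 * 0.5, 1e-3))] * d
    v0.append(math.log(s0))
    if use_ar1:
        v0.append(0.2)
    v0 = np.asarray(v0)

    rng = np.random.default_rng(options.seed)
    best = None
    for r in range(max(options.n_restarts, 1)):
        start = v0 if r == 0 else v0 + 0.3 * rng.standard_normal(len(v0))
        res = minimize(
            profile_nll,
            start,
            method="L-BFGS-B",
            bounds=[(-8, 4)] * n_re_par + [(-8, 4)] + ([(-3, 3)] if use_ar1 else []),
            options={"maxiter": options.maxiter, "ftol": 1e-12, "gtol": options.gtol},
        )
        if best is None or res.fun < best.fun:
            best = res

    nll, beta, XtVX = profile_nll(best.x, want_beta=True)
    L, sigma, rho = unpack(best.x)
    cov_hat = L @ L.T if d else np.zeros((0, 0))
    beta_cov = np.linalg.pinv(XtVX)

    estimates = {nm: float(b) for nm, b in zip(names, beta)}
    ses = {nm: float(se) for nm, se in zip(names, np.sqrt(np.diag(beta_cov)))}
    estimates["sigma"] = sigma
    ses["sigma"] = float("nan")
    if use_ar1:
        estimates["rho"] = rho
        ses["rho"] = float("nan")
    for j, p in enumerate(spec.random_terms):
        estimates[f"sd(age^{p})"] = math.sqrt(cov_hat[j, j])

    # Wald SEs for variance parameters via the profile-likelihood Hessian
    try:
        H = _fd_hessian(profile_nll, best.x, options.hessian_step)
        vcov = np.linalg.pinv(H)
        se_v = np.sqrt(np.clip(np.diag(vcov), 0, None))
        ses["sigma"] = sigma * se_v[n_re_par]
        if use_ar1:
            ses["rho"] = (1 - rho**2) * se_v[n_re_par + 1]
    except Exception:
        pass

    # empirical-Bayes random effects: b_i = Sigma Z' V^{-1} (y - X beta)
    eb = None
    if d:
        eb = {}
        for tr, X, Z, y in zip(data.trajectories, Xs, Zs, ys):
            m = len(y)
            if use_ar1 and rho != 0.0:
                idx = np.arange(m)
                R = rho ** np.abs(idx[:, None] - idx[None, :])
            else:
                R = np.eye(m)
            V = sigma**2 * R + Z @ cov_hat @ Z.T
            r = y - X @ beta
            b = cov_hat @ Z.T @ np.linalg.solve(V, r)
            eb[tr.child_id] = {
                f"age^{p}": float(b[j]) for j, p in enumerate(spec.random_terms)
            }

    k = p_fix + n_var
    loglik = -float(nll)
    aic, bic = _information_criteria(loglik, k, data.n_obs)
    return FitResult(
        estimates=estimates,
        standard_errors=ses,
        loglik=loglik,
        n_params=k,
        n_obs=data.n_obs,
        aic=aic,
        bic=bic,
        converged=bool(best.success) and best.fun < _BIG,
        label=label
        or f"lmm[order{spec.poly_order},re{spec.random_terms},{spec.error_cov}]",
        message=str(best.message),
        random_effects_cov_hat=cov_hat,
        re_names=tuple(f"age^{p}" for p in spec.random_terms),
        empirical_bayes=eb,
        parameterization="lmm",
        extra={"spec": spec, "beta": beta.tolist(), "theta": best.x.tolist()},
    )
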