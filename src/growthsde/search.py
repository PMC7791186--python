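"""AIC/BIC-guided model search with p-value trimming.

The search enumerates candidate model formulations — drift polynomial
orders up to cubic (with or without mean reversion) for the SDE family,
age-polynomial orders up to quartic for the LMM family, plus candidate
random-effect sets and covariance structures — fits each, then iteratively
drops the fixed-effect term with the largest Wald p-value while that
p-value exceeds the trimming threshold (default 0.1).  All successful fits
are returned ranked by AIC, with BIC alongside; candidates that fail to
fit are logged and skipped, never fatal.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np

from .fit import CohortData, FitOptions, FitResult, fit_mle, fit_mixed_sde
from .lmm import LMMSpec, fit_lmm
from .models import SDEModelSpec

__all__ = ["SearchRules", "model_search", "trim_sde_fit", "trim_lmm_fit"]

log = logging.getLogger(__name__)

_ORDER_OF = {"a2": 0, "a3": 1, "a4": 2, "a5": 3}


@dataclass(frozen=True)
class SearchRules:
    """Enumeration and trimming rules for ``model_search``."""

    p_trim: float = 0.1
    # SDE family
    drift_orders: tuple = (0, 1, 2, 3)
    mean_reversion: tuple = (True,)
    re_candidates: tuple = ((),)
    re_cov_structures: tuple = ("diagonal",)
    # LMM family
    lmm_orders: tuple = (1, 2, 3, 4)
    lmm_random_terms: tuple = ((0, 1),)
    lmm_error_cov: tuple = ("AR1",)
    lmm_site_interactions: tuple = ((),)


def _sde_template(order: int, mean_reversion: bool) -> SDEModelSpec:
    params = {"s": 1.0}
    if mean_reversion:
        params["a1"] = -0.5
    for name, o in _ORDER_OF.items():
        if o <= order:
            params[name] = 0.0
    return SDEModelSpec(
        drift_order=order, mean_reversion=mean_reversion, params=params
    )


def _drop_param(template: SDEModelSpec, name: str) -> SDEModelSpec:
    params = {k: v for k, v in template.params.items() if k != name}
    drift_order = max(
        (_ORDER_OF[k] for k in params if k in _ORDER_OF), default=0
    )
    return SDEModelSpec(
        drift_order=drift_order,
        mean_reversion="a1" in params,
        params=params,
        site_offsets=template.site_offsets,
        random_effect_names=template.random_effect_names,
    )


def trim_sde_fit(
    template: SDEModelSpec,
    cohort,
    p_trim: float = 0.1,
    re_names=(),
    re_cov_structure: str = "diagonal",
    options: FitOptions | None = None,
):
    """Fit, then drop the highest-p drift term while its Wald p > p_trim.

    Returns ``(fit, trimmed_names)``.  Terms carrying random effects and
    the diffusion are never trimmed.
    """
    trimmed = []
    while True:
        if re_names:
            fit = fit_mixed_sde(
                template,
                cohort,
                re_names,
                re_cov_structure=re_cov_structure,
                options=options,
                parameterization="natural",
            )
        else:
            fit = fit_mle(template, cohort, options=options, parameterization="natural")
        candidates = {
            n: p
            for n, p in fit.p_values.items()
            if n in template.params and n != "s" and n not in re_names
            and np.isfinite(p)
        }
        if not candidates:
            return fit, trimmed
        worst = max(candidates, key=candidates.get)
        if candidates[worst] <= p_trim or len(template.params) <= 2:
            return fit, trimmed
        trimmed.append((worst, candidates[worst]))
        template = _drop_param(template, worst)


def trim_lmm_fit(
    spec: LMMSpec,
    cohort,
    p_trim: float = 0.1,
    options: FitOptions | None = None,
):
    """Fit the LMM, then drop the highest-p fixed term (never the
    intercept) while its Wald p > p_trim."""
    trimmed = []
    while True:
        fit = fit_lmm(spec, cohort, options=options)
        candidates = {
            n: p
            for n, p in fit.p_values.items()
            if (n.startswith("age^") or n.startswith("site"))
            and not n.startswith("sd(")
            and n not in ("age^0", "sigma", "rho")
            and np.isfinite(p)
        }
        if not candidates:
            return fit, trimmed
        worst = max(candidates, key=candidates.get)
        if candidates[worst] <= p_trim:
            return fit, trimmed
        trimmed.append((worst, candidates[worst]))
        spec = LMMSpec(
            poly_order=spec.poly_order,
            site_interactions=spec.site_interactions,
            random_terms=spec.random_terms,
            re_cov=spec.re_cov,
            error_cov=spec.error_cov,
            dropped_terms=spec.dropped_terms + (worst,),
        )


def model_search(
    cohort,
    family: str,
    rules: SearchRules | None = None,
    options: FitOptions | None = None,
) -> list:
    """Enumerate, fit, trim and rank candidate models by AIC.

    ``family`` is 'sde' or 'lmm'.  Returns the list of successful
    :class:`FitResult` objects sorted by AIC (ascending); each result's
    ``extra['trimmed']`` records the terms removed by p-value trimming.
    """
    rules = rules or SearchRules()
    data = CohortData.ensure(cohort)
    fits: list = []
    if family == "sde":
        combos = itertools.product(
            rules.drift_orders,
            rules.mean_reversion,
            rules.re_candidates,
            rules.re_cov_structures,
        )
        for order, mr, re_names, structure in combos:
            if re_names and structure not in ("diagonal", "unstructured"):
                continue
            template = _sde_template(order, mr)
            try:
                fit, trimmed = trim_sde_fit(
                    template,
                    data,
                    p_trim=rules.p_trim,
                    re_names=re_names,
                    re_cov_structure=structure,
                    options=options,
                )
                fit.extra["trimmed"] = trimmed
                fits.append(fit)
            except Exception as exc:  # candidate failure is not fatal
                log.warning(
                    "SDE candidate order=%s mr=%s re=%s failed: %s",
                    order, mr, re_names, exc,
                )
    elif family == "lmm":
        combos = itertools.product(
            rules.lmm_orders,
            rules.lmm_random_terms,
            rules.lmm_error_cov,
            rules.lmm_site_interactions,
        )
        for order, rterms, err, inter in combos:
            rterms = tuple(p for p in rterms if p <= order)
            spec = LMMSpec(
                poly_order=order,
                site_interactions=inter,
                random_terms=rterms,
                error_cov=err,
            )
            try:
                fit, trimmed = trim_lmm_fit(
                    spec, data, p_trim=rules.p_trim, options=options
                )
                fit.extra["trimmed"] = trimmed
                fits.append(fit)
            except Exception as exc:
                log.warning("LMM candidate order=%s failed: %s", order, exc)
    else:
        raise ValueError("family must be 'sde' or 'lmm'")
    fits.sort(key=lambda f: f.aic)
    return fits
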