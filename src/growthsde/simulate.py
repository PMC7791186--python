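"""Trajectory simulation and the synthetic-cohort generator.

Simulation serves two roles:

* **Exact sampling** from the Gaussian slice density (``sample_transition``,
  ``simulate_trajectory``) — the reference way to generate data from a
  linear-SDE model, bias-free at any visit spacing.
* **Euler–Maruyama discretization** (``euler_maruyama``) — a brute-force
  path integrator used as an independent oracle when verifying the
  closed-form slice densities; its bias vanishes as the step shrinks.

``simulate_cohort`` generates a synthetic two-site longitudinal study with
the structure of a birth-cohort anthropometry data set: a monthly visit
schedule over ages 0–24 months, visit-age jitter within a ±14 day window,
occasional missed visits, per-child random effects on model parameters, and
site effects taken from the model specification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .models import (
    AgePoint,
    SDEModelSpec,
    drift,
    ou_model,
    slice_density,
    slice_mean_var,
)

__all__ = [
    "DAYS_PER_MONTH",
    "Trajectory",
    "CohortDesign",
    "sample_transition",
    "euler_maruyama",
    "euler_maruyama_moments",
    "simulate_trajectory",
    "simulate_cohort",
    "cohort_to_frame",
    "random_linear_sde",
]


def random_linear_sde(rng, family: str = "cubic") -> SDEModelSpec:
    """Random member of the linear-SDE family, for verification sweeps.

    ``family='ou'`` draws a mean-reverting OU model; ``family='cubic'``
    draws a cubic-drift model with mean reversion.  Parameter ranges span
    the magnitudes typical of growth z-score dynamics.
    """
    if family == "ou":
        return ou_model(
            rng.uniform(0.3, 2.5), rng.uniform(-2, 1), rng.uniform(0.2, 1.2)
        )
    params = {
        "a1": rng.uniform(-2.0, -0.1),
        "a2": rng.uniform(-0.5, 0.5),
        "a3": rng.uniform(-0.1, 0.1),
        "a4": rng.uniform(-0.02, 0.02),
        "a5": rng.uniform(-0.002, 0.002),
        "s": rng.uniform(0.2, 1.0),
    }
    return SDEModelSpec(drift_order=3, mean_reversion=True, params=params)

DAYS_PER_MONTH = 30.4375  # mean Gregorian month length
JITTER_CAP_MONTHS = 14.0 / DAYS_PER_MONTH


@dataclass(frozen=True)
class Trajectory:
    """Ordered visit sequence for one child: (age, z-score) pairs plus site."""

    child_id: str
    site: str | None
    points: tuple

    def __post_init__(self):
        pts = tuple(AgePoint(*p).validate() for p in self.points)
        object.__setattr__(self, "points", pts)
        ages = [p.age for p in pts]
        if any(b <= a for a, b in zip(ages, ages[1:])):
            raise ValueError(
                f"trajectory {self.child_id!r}: ages must be strictly increasing"
            )

    def __len__(self) -> int:
        return len(self.points)

    @property
    def ages(self) -> np.ndarray:
        return np.array([p.age for p in self.points])

    @property
    def values(self) -> np.ndarray:
        return np.array([p.value for p in self.points])


@dataclass(frozen=True)
class CohortDesign:
    """Design of a synthetic longitudinal cohort.

    Defaults emulate a two-site birth cohort with monthly anthropometry
    visits over 0–24 months: 25 scheduled visits per child, visit ages
    jittered within a ±14-day window (truncated normal, sd 5 days), and a
    2.8% chance of missing any visit after the first, which puts ~85% of
    children at 24 or more completed visits — the completeness level
    typical of intensive birth-cohort follow-up.
    """

    n_children_per_site: int
    sites: tuple = ("site_a", "site_b")
    visit_ages: tuple = tuple(float(a) for a in range(25))
    age_jitter_sd: float = 5.0 / DAYS_PER_MONTH
    p_visit_missing: float = 0.028
    random_effects_cov: np.ndarray | None = None
    initial_mean: float | Mapping[str, float] = 0.0
    initial_sd: float | Mapping[str, float] = 1.0
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "sites", tuple(self.sites))
        object.__setattr__(
            self, "visit_ages", tuple(float(a) for a in self.visit_ages)
        )
        if not 0.0 <= self.p_visit_missing <= 1.0:
            raise ValueError("p_visit_missing must be in [0, 1]")
        if self.age_jitter_sd < 0:
            raise ValueError("age_jitter_sd must be >= 0")
        if len(self.visit_ages) == 0:
            raise ValueError("visit schedule must be non-empty")
        if any(
            b <= a for a, b in zip(self.visit_ages, self.visit_ages[1:])
        ):
            raise ValueError("visit_ages must be strictly increasing")
        if self.random_effects_cov is not None:
            cov = np.atleast_2d(np.asarray(self.random_effects_cov, float))
            if not np.allclose(cov, cov.T):
                raise ValueError("random_effects_cov must be symmetric")
            if np.any(np.linalg.eigvalsh(cov) < -1e-10):
                raise ValueError("random_effects_cov must be positive semi-definite")
            object.__setattr__(self, "random_effects_cov", cov)

    def _site_scalar(self, value, site) -> float:
        if isinstance(value, Mapping):
            return float(value[site])
        return float(value)


def sample_transition(
    model: SDEModelSpec, start: AgePoint, t1: float, site=None, rng=None
) -> float:
    """One exact draw from the slice density of X at t1 given start."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    d = slice_density(model, start, t1, site)
    if d.variance == 0.0:
        return d.mean
    return d.mean + math.sqrt(d.variance) * rng.standard_normal()


def euler_maruyama(
    model: SDEModelSpec,
    start: AgePoint,
    t1: float,
    site=None,
    step: float = 1e-3,
    rng=None,
) -> float:
    """Endpoint of one Euler–Maruyama path from ``start`` to age ``t1``.

    The last step is shortened to land exactly on ``t1``.  This integrator
    is deliberately naive — it exists as a discretized oracle against which
    the exact closed-form transitions are verified.
    """
    start = AgePoint(*start).validate()
    if step <= 0:
        raise ValueError("step must be > 0")
    dt_total = t1 - start.age
    if dt_total < 0:
        raise ValueError("t1 must be >= start age")
    if dt_total == 0.0:
        return start.value
    if step >= dt_total:
        raise ValueError(
            f"step {step} must be smaller than the elapsed time {dt_total}"
        )
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    p = model.params_for_site(site)
    s = p["s"]
    t, x = start.age, start.value
    while t < t1 - 1e-15:
        h = min(step, t1 - t)
        x = x + drift(model, t, x, site) * h + s * math.sqrt(h) * rng.standard_normal()
        t += h
    return x


def euler_maruyama_moments(
    model: SDEModelSpec,
    start: AgePoint,
    t1: float,
    site=None,
    step: float = 1e-3,
    n_paths: int = 10_000,
    rng=None,
):
    """Vectorized Euler–Maruyama endpoint sample over many paths.

    Returns the endpoint array (length ``n_paths``); moments and Monte-Carlo
    standard errors are left to the caller.
    """
    start = AgePoint(*start).validate()
    if step <= 0:
        raise ValueError("step must be > 0")
    dt_total = t1 - start.age
    if step >= dt_total:
        raise ValueError("step must be smaller than the elapsed time")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    p = model.params_for_site(site)
    a1, s = p["a1"], p["s"]
    b = (p["a2"], p["a3"], p["a4"], p["a5"])
    n_full, rem = divmod(dt_total, step)
    steps = [step] * int(round(n_full))
    if rem > 1e-12:
        steps.append(rem)
    x = np.full(n_paths, start.value)
    t = start.age
    for h in steps:
        pt = ((b[3] * t + b[2]) * t + b[1]) * t + b[0]
        x += (pt + a1 * x) * h + s * math.sqrt(h) * rng.standard_normal(n_paths)
        t += h
    return x


def simulate_trajectory(
    model: SDEModelSpec,
    visit_ages: Sequence[float],
    site=None,
    rng=None,
    initial_mean: float = 0.0,
    initial_sd: float = 1.0,
    child_id: str = "child",
) -> Trajectory:
    """Simulate one trajectory by exact transitions over the given ages.

    The first value is drawn from N(initial_mean, initial_sd^2); subsequent
    values are exact draws from the slice density between consecutive ages.
    """
    ages = [float(a) for a in visit_ages]
    if not ages:
        raise ValueError("visit schedule must be non-empty")
    if any(b <= a for a, b in zip(ages, ages[1:])):
        raise ValueError("visit ages must be strictly increasing")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    x0 = initial_mean + initial_sd * rng.standard_normal() if initial_sd > 0 else initial_mean
    points = [AgePoint(ages[0], float(x0))]
    for t1 in ages[1:]:
        x1 = sample_transition(model, points[-1], t1, site=site, rng=rng)
        points.append(AgePoint(t1, float(x1)))
    return Trajectory(child_id=child_id, site=site, points=tuple(points))


def _truncated_jitter(rng, sd: float, lo: float, hi: float) -> float:
    """Draw from N(0, sd^2) truncated to [lo, hi] by rejection."""
    if sd == 0.0:
        return 0.0
    for _ in range(1000):
        j = sd * rng.standard_normal()
        if lo <= j <= hi:
            return j
    return float(np.clip(sd * rng.standard_normal(), lo, hi))


def _child_model(model: SDEModelSpec, re_values: Mapping[str, float]) -> SDEModelSpec:
    """Apply per-child random-effect offsets: additive on drift params, on
    log(s) for the diffusion."""
    params = dict(model.params)
    for name, b in re_values.items():
        if name == "s":
            params["s"] = math.exp(math.log(params["s"]) + b)
        else:
            params[name] = params.get(name, 0.0) + b
    return SDEModelSpec(
        drift_order=model.drift_order,
        mean_reversion=model.mean_reversion,
        params=params,
        site_offsets=model.site_offsets,
        random_effect_names=model.random_effect_names,
    )


def simulate_cohort(model: SDEModelSpec, design: CohortDesign) -> list:
    """Simulate a full multi-site cohort of trajectories.

    Per child: random effects (over ``model.random_effect_names``) are drawn
    once from N(0, design.random_effects_cov) and held fixed; visit ages are
    the schedule plus truncated-normal jitter capped at ±14 days (never
    below age 0); each visit after the first is independently missing with
    probability ``p_visit_missing``.
    """
    rng = np.random.default_rng(design.seed)
    re_names = model.random_effect_names
    cov = design.random_effects_cov
    if re_names and cov is None:
        raise ValueError(
            "model declares random effects but design.random_effects_cov is None"
        )
    if re_names and cov.shape != (len(re_names), len(re_names)):
        raise ValueError(
            f"random_effects_cov shape {cov.shape} does not match "
            f"{len(re_names)} random effect(s) {list(re_names)}"
        )
    chol = None
    if re_names:
        # PSD (possibly singular) covariance: eigendecomposition square root
        w, v = np.linalg.eigh(cov)
        chol = v * np.sqrt(np.clip(w, 0.0, None))

    trajectories = []
    width = len(str(max(design.n_children_per_site - 1, 1)))
    for site in design.sites:
        init_mean = design._site_scalar(design.initial_mean, site)
        init_sd = design._site_scalar(design.initial_sd, site)
        for i in range(design.n_children_per_site):
            child_id = f"{site}-{i:0{width}d}"
            if re_names:
                b = chol @ rng.standard_normal(len(re_names))
                child = _child_model(model, dict(zip(re_names, b)))
            else:
                child = model
            ages = []
            for k, sched in enumerate(design.visit_ages):
                if k > 0 and rng.random() < design.p_visit_missing:
                    continue
                lo = max(-JITTER_CAP_MONTHS, -sched)
                ages.append(
                    sched + _truncated_jitter(rng, design.age_jitter_sd, lo, JITTER_CAP_MONTHS)
                )
            trajectories.append(
                simulate_trajectory(
                    child,
                    ages,
                    site=site,
                    rng=rng,
                    initial_mean=init_mean,
                    initial_sd=init_sd,
                    child_id=child_id,
                )
            )
    return trajectories


def cohort_to_frame(trajectories) -> "pandas.DataFrame":
    """Long-format table: one row per visit with columns
    child_id, site, age_months, zwfl."""
    import pandas as pd

    rows = [
        (tr.child_id, tr.site, p.age, p.value)
        for tr in trajectories
        for p in tr.points
    ]
    return pd.DataFrame(rows, columns=["child_id", "site", "age_months", "zwfl"])
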