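"""Linear-SDE model family for growth z-score trajectories.

The family modelled here is the narrow-sense linear stochastic differential
equation

    dX_t = (p(t) + a1 * X_t) dt + s dW_t,      p(t) = a2 + a3*t + a4*t^2 + a5*t^3,

where ``X_t`` is a growth z-score (weight-for-length) at age ``t`` months,
``p(t)`` is a polynomial drift in age of order 0-3, the optional ``a1 * X_t``
term produces mean reversion, and ``s > 0`` is a constant diffusion scaling a
Wiener process.  The Ornstein-Uhlenbeck (OU) process
``dX = alpha*(beta - X) dt + sigma dW`` is the special case
``a1 = -alpha, a2 = alpha*beta, s = sigma`` with drift order 0.

Because drift is linear in ``X`` and diffusion is constant, the transition
("slice") density of ``X_{t1}`` given ``(x0, t0)`` is exactly Gaussian:

    mean     = e^{a1 (t1-t0)} x0 + int_{t0}^{t1} e^{a1 (t1-u)} p(u) du
    variance = s^2 (e^{2 a1 (t1-t0)} - 1) / (2 a1)

with the obvious ``a1 -> 0`` limits.  The polynomial integral is evaluated in
closed form through the helper integrals ``phi_j(a, dt) = int_0^dt e^{a v} v^j dv``,
computed by a stable series for small ``|a*dt|`` and a recurrence otherwise, so
the evaluation is uniformly accurate across the mean-reverting and
drift-only regimes.

Site (cohort location) enters as additive offsets on drift parameters and as
an additive offset on ``log s`` for the diffusion, which keeps ``s`` positive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import yaml

__all__ = [
    "AgePoint",
    "SliceDensity",
    "SDEModelSpec",
    "ou_model",
    "drift",
    "slice_density",
    "ou_covariance",
]

#: ordered names of the drift polynomial coefficients (constant .. cubic term)
DRIFT_POLY_NAMES = ("a2", "a3", "a4", "a5")
PARAM_NAMES = ("a1",) + DRIFT_POLY_NAMES + ("s",)

# binomial coefficients C(k, j) for k, j <= 3, used to re-centre p at t1
_BINOM = np.array(
    [[1, 0, 0, 0], [1, 1, 0, 0], [1, 2, 1, 0], [1, 3, 3, 1]], dtype=float
)

_SERIES_CUT = 0.75  # |a*dt| below which the series evaluation of phi_j is used
_SERIES_TERMS = 30


class AgePoint(NamedTuple):
    """A single observation: age in months and growth z-score value."""

    age: float
    value: float

    def validate(self) -> "AgePoint":
        if not (math.isfinite(self.age) and self.age >= 0):
            raise ValueError(f"age must be finite and >= 0, got {self.age}")
        if not math.isfinite(self.value):
            raise ValueError(f"value must be finite, got {self.value}")
        return self


class SliceDensity(NamedTuple):
    """Gaussian transition law of X at t1 given (x0, t0): mean and variance.

    Variance is zero exactly when no time has elapsed; the density is then
    degenerate at ``mean``.
    """

    mean: float
    variance: float

    def logpdf(self, x: float) -> float:
        if self.variance == 0.0:
            return math.inf if x == self.mean else -math.inf
        return -0.5 * (
            math.log(2.0 * math.pi * self.variance)
            + (x - self.mean) ** 2 / self.variance
        )

    def pdf(self, x: float) -> float:
        lp = self.logpdf(x)
        return math.exp(lp) if lp != math.inf else math.inf


def _phi_table(a, dt, jmax: int):
    """phi_j(a, dt) = int_0^dt e^{a v} v^j dv for j = 0..jmax, vectorized.

    Uses a truncated power series when |a*dt| is small (removable singularity
    at a=0) and the integration-by-parts recurrence otherwise.
    """
    a = np.asarray(a, dtype=float)
    dt = np.asarray(dt, dtype=float)
    a, dt = np.broadcast_arrays(a, dt)
    w = a * dt
    small = np.abs(w) < _SERIES_CUT
    any_small = bool(np.any(small))
    all_small = bool(np.all(small))
    a_safe = np.where(small, 1.0, a)  # avoid 0-division in the unused branch

    # series: phi_j = dt^{j+1} * sum_m w^m / (m! (j+m+1))
    series = None
    if any_small:
        series = []
        wm = np.ones_like(w)  # w^m / m!
        sums = [np.zeros_like(w) for _ in range(jmax + 1)]
        for m in range(_SERIES_TERMS):
            for j in range(jmax + 1):
                sums[j] += wm / (j + m + 1)
            wm = wm * w / (m + 1)
        dt_pow = dt.copy()
        for j in range(jmax + 1):
            series.append(dt_pow * sums[j])
            dt_pow = dt_pow * dt
        if all_small:
            return series

    # recurrence: phi_0 = expm1(w)/a ; phi_j = (dt^j e^w - j phi_{j-1}) / a
    with np.errstate(over="ignore", invalid="ignore"):
        ew = np.exp(np.where(small, 0.0, w))
        rec = [np.where(small, 0.0, np.expm1(np.where(small, 0.0, w)) / a_safe)]
        dtj = dt.copy()
        for j in range(1, jmax + 1):
            rec.append((dtj * ew - j * rec[j - 1]) / a_safe)
            dtj = dtj * dt
    if not any_small:
        return rec
    return [np.where(small, series[j], rec[j]) for j in range(jmax + 1)]


def slice_mean_var(a1, b, s, t0, t1, x0):
    """Vectorized slice-density moments for the linear-SDE family.

    Parameters
    ----------
    a1 : array_like
        Coefficient of the linear (mean-reversion) term; 0 disables it.
    b : sequence of 4 array_like
        Drift polynomial coefficients ``(b0, b1, b2, b3)`` so that
        ``p(u) = b0 + b1 u + b2 u^2 + b3 u^3``.
    s : array_like
        Diffusion (must be > 0, not checked here).
    t0, t1, x0 : array_like
        Start age, end age (t1 >= t0) and start value.

    Returns
    -------
    mean, variance : ndarray
    """
    a1 = np.asarray(a1, dtype=float)
    t0 = np.asarray(t0, dtype=float)
    t1 = np.asarray(t1, dtype=float)
    x0 = np.asarray(x0, dtype=float)
    s = np.asarray(s, dtype=float)
    b = [np.asarray(bk, dtype=float) for bk in b]
    dt = t1 - t0

    phis = _phi_table(a1, dt, 3)
    # re-centre p at t1: p(t1 - v) = sum_j c_j v^j with
    # c_j = (-1)^j sum_{k>=j} b_k C(k,j) t1^{k-j}
    drift_int = np.zeros(np.broadcast(a1, dt, x0, *b).shape)
    t1_pows = [np.ones_like(t1), t1, t1 * t1, t1 * t1 * t1]
    for j in range(4):
        c_j = np.zeros_like(drift_int)
        for k in range(j, 4):
            c_j = c_j + b[k] * _BINOM[k, j] * t1_pows[k - j]
        if j % 2:
            c_j = -c_j
        drift_int = drift_int + c_j * phis[j]

    mean = np.exp(a1 * dt) * x0 + drift_int
    variance = s * s * _phi_table(2.0 * a1, dt, 0)[0]
    return mean, variance


def _require_valid_params(
    drift_order: int, mean_reversion: bool, params: Mapping[str, float]
) -> None:
    if drift_order not in (0, 1, 2, 3):
        raise ValueError(f"drift_order must be 0-3, got {drift_order}")
    allowed = set(DRIFT_POLY_NAMES[: drift_order + 1]) | {"s"}
    if mean_reversion:
        allowed.add("a1")
    unknown = set(params) - set(PARAM_NAMES)
    if unknown:
        raise ValueError(f"unknown parameter names: {sorted(unknown)}")
    extra = set(params) - allowed
    if extra:
        raise ValueError(
            f"parameters {sorted(extra)} not admitted by drift_order="
            f"{drift_order}, mean_reversion={mean_reversion}"
        )
    if "s" not in params:
        raise ValueError("diffusion parameter 's' is required")
    if not params["s"] > 0:
        raise ValueError(f"diffusion s must be > 0, got {params['s']}")


@dataclass(frozen=True)
class SDEModelSpec:
    """A member of the linear-SDE family dX = (p(t) + a1 X) dt + s dW.

    Parameters
    ----------
    drift_order : int
        Order (0-3) of the age polynomial ``p(t)``.
    mean_reversion : bool
        Whether the ``a1 * X`` term is included.  When False, ``a1`` is
        exactly zero and must be absent from ``params``.
    params : dict
        Named parameter values.  Keys are a subset of
        ``("a1", "a2", "a3", "a4", "a5", "s")``; unused entries are absent.
    site_offsets : dict
        ``{param_name: {site_label: offset}}``.  Offsets are additive on the
        drift parameters and additive on ``log s`` for the diffusion.
    random_effect_names : tuple
        Parameter names that carry child-level random effects (used by the
        mixed-effects fitter and the cohort simulator).
    """

    drift_order: int
    mean_reversion: bool
    params: Mapping[str, float]
    site_offsets: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    random_effect_names: tuple = ()

    def __post_init__(self):
        _require_valid_params(self.drift_order, self.mean_reversion, self.params)
        object.__setattr__(self, "params", dict(self.params))
        object.__setattr__(
            self,
            "site_offsets",
            {k: dict(v) for k, v in self.site_offsets.items()},
        )
        object.__setattr__(
            self, "random_effect_names", tuple(self.random_effect_names)
        )
        for name in self.site_offsets:
            if name not in PARAM_NAMES:
                raise ValueError(f"site offset on unknown parameter {name!r}")
        for name in self.random_effect_names:
            if name not in PARAM_NAMES:
                raise ValueError(f"random effect on unknown parameter {name!r}")
        for site in self.known_sites:
            p = self.params_for_site(site)
            if not p["s"] > 0:
                raise ValueError(
                    f"diffusion must stay positive after site offset "
                    f"(site {site!r} gives s={p['s']})"
                )

    # ------------------------------------------------------------------
    @property
    def known_sites(self) -> tuple:
        sites: set = set()
        for offsets in self.site_offsets.values():
            sites.update(offsets)
        return tuple(sorted(sites))

    def _check_site(self, site) -> None:
        known = self.known_sites
        if known and site not in known:
            raise KeyError(
                f"unknown site label {site!r}; model defines offsets for "
                f"{list(known)}"
            )

    def params_for_site(self, site=None) -> dict:
        """Full parameter dict (zeros for absent drift terms), site applied."""
        self._check_site(site)
        full = {name: 0.0 for name in PARAM_NAMES}
        full.update(self.params)
        if site is not None:
            for name, offsets in self.site_offsets.items():
                off = offsets.get(site, 0.0)
                if name == "s":
                    full["s"] = math.exp(math.log(full["s"]) + off)
                else:
                    full[name] = full[name] + off
        return full

    @property
    def is_ou(self) -> bool:
        return self.mean_reversion and self.drift_order == 0

    def ou_params(self, site=None) -> tuple:
        """(alpha, beta, sigma) view of an OU-form model (a1 < 0)."""
        if not self.is_ou:
            raise ValueError("model is not in OU form (needs mean reversion, drift order 0)")
        p = self.params_for_site(site)
        alpha = -p["a1"]
        if alpha <= 0:
            raise ValueError("OU view requires a1 < 0 (positive reversion speed)")
        return alpha, p["a2"] / alpha, p["s"]

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "drift_order": self.drift_order,
            "mean_reversion": self.mean_reversion,
            "params": dict(self.params),
            "site_offsets": {k: dict(v) for k, v in self.site_offsets.items()},
            "random_effect_names": list(self.random_effect_names),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SDEModelSpec":
        return cls(
            drift_order=int(d["drift_order"]),
            mean_reversion=bool(d["mean_reversion"]),
            params={k: float(v) for k, v in d["params"].items()},
            site_offsets={
                k: {sk: float(sv) for sk, sv in v.items()}
                for k, v in d.get("site_offsets", {}).items()
            },
            random_effect_names=tuple(d.get("random_effect_names", ())),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SDEModelSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def ou_model(
    alpha: float,
    beta: float,
    sigma: float,
    site_offsets: Mapping[str, Mapping[str, float]] | None = None,
    random_effect_names: Iterable[str] = (),
) -> SDEModelSpec:
    """OU process dX = alpha*(beta - X) dt + sigma dW as an SDEModelSpec.

    ``alpha`` is the speed of reversion (> 0), ``beta`` the long-term mean and
    ``sigma`` the diffusion.
    """
    if alpha <= 0:
        raise ValueError("OU speed of reversion alpha must be > 0")
    return SDEModelSpec(
        drift_order=0,
        mean_reversion=True,
        params={"a1": -alpha, "a2": alpha * beta, "s": sigma},
        site_offsets=site_offsets or {},
        random_effect_names=tuple(random_effect_names),
    )


def _poly_coeffs(params: Mapping[str, float]) -> list:
    return [params["a2"], params["a3"], params["a4"], params["a5"]]


def drift(model: SDEModelSpec, t: float, x: float, site=None) -> float:
    """Drift rate p(t) + a1*x (z-score per month) at age t, value x."""
    if t < 0:
        raise ValueError(f"age must be >= 0, got {t}")
    p = model.params_for_site(site)
    b0, b1, b2, b3 = _poly_coeffs(p)
    return ((b3 * t + b2) * t + b1) * t + b0 + p["a1"] * x


def slice_density(
    model: SDEModelSpec, start: AgePoint, t1: float, site=None
) -> SliceDensity:
    """Gaussian transition density of X at age t1 given start=(age, value).

    Raises
    ------
    ValueError
        If ``t1`` precedes the start age (time must not run backwards).
    """
    start = AgePoint(*start).validate()
    if t1 < start.age:
        raise ValueError(
            f"time must not run backwards: t1={t1} < t0={start.age}"
        )
    p = model.params_for_site(site)
    mean, var = slice_mean_var(
        p["a1"], _poly_coeffs(p), p["s"], start.age, t1, start.value
    )
    return SliceDensity(float(mean), max(float(var), 0.0))


def ou_covariance(
    model: SDEModelSpec, t0: float, s_time: float, t_time: float, site=None
) -> float:
    """Covariance of an OU process (started as a constant at t0) at two ages.

    For dX = alpha*(beta - X) dt + sigma dW started at a constant at ``t0``,

        Cov(X_s, X_t) = e^{-(s+t) alpha} (e^{2 alpha min(s,t)} - e^{2 t0 alpha})
                        * sigma^2 / (2 alpha),

    symmetric in the two ages.
    """
    alpha, _, sigma = model.ou_params(site)
    if t0 > min(s_time, t_time):
        raise ValueError("t0 must precede both time points")
    m = min(s_time, t_time)
    return (
        math.exp(-(s_time + t_time) * alpha)
        * (math.exp(2.0 * alpha * m) - math.exp(2.0 * t0 * alpha))
        * sigma**2
        / (2.0 * alpha)
    )
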