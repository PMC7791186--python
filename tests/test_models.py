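"""Slice densities, drift evaluation and model-spec invariants."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from growthsde import AgePoint, SDEModelSpec, drift, ou_covariance, ou_model, slice_density
from growthsde.models import slice_mean_var

from conftest import random_linear_sde


def ou_closed_form(alpha, beta, sigma, t0, t1, x0):
    """Independent closed-form OU transition (mean, variance) oracle."""
    dt = t1 - t0
    mean = math.exp(-alpha * dt) * (x0 - beta) + beta
    var = (1.0 - math.exp(-2.0 * alpha * dt)) * sigma**2 / (2.0 * alpha)
    return mean, var


class TestDrift:
    def test_ou_drift_is_alpha_times_gap(self):
        m = ou_model(1.0, 0.0, 1.0)
        assert drift(m, t=0.0, x=2.0) == pytest.approx(-2.0)

    def test_drift_vanishes_at_stationary_point(self, cubic):
        p = cubic.params
        t = 7.0
        pt = p["a2"] + p["a3"] * t + p["a4"] * t**2 + p["a5"] * t**3
        x_star = pt / (-p["a1"])
        assert drift(cubic, t, x_star) == pytest.approx(0.0, abs=1e-12)

    def test_cubic_drift_matches_direct_polynomial(self):
        a = (-0.5, 0.1, 0.02, -0.003, 0.0001)
        m = SDEModelSpec(
            drift_order=3,
            mean_reversion=True,
            params={"a1": a[0], "a2": a[1], "a3": a[2], "a4": a[3], "a5": a[4], "s": 1.0},
        )
        t, x = 12.0, -1.0
        expected = a[1] + a[2] * t + a[3] * t**2 + a[4] * t**3 + a[0] * x
        assert drift(m, t, x) == pytest.approx(expected, rel=1e-14)

    def test_unknown_site_label_is_named_in_error(self):
        m = ou_model(1.0, 0.0, 1.0, site_offsets={"a2": {"venda": 0.1}})
        with pytest.raises(KeyError, match="nowhere"):
            drift(m, 1.0, 0.0, site="nowhere")


class TestSliceDensity:
    def test_zero_elapsed_time_is_degenerate(self, cubic):
        d = slice_density(cubic, AgePoint(3.0, -1.2), 3.0)
        assert d.mean == pytest.approx(-1.2)
        assert d.variance == 0.0

    def test_ou_stationary_limit(self):
        m = ou_model(1.0, -0.5, 1.0)
        d = slice_density(m, AgePoint(0.0, 2.0), 60.0)
        assert d.mean == pytest.approx(-0.5, abs=1e-10)
        assert d.variance == pytest.approx(0.5, abs=1e-10)

    def test_ou_closed_form_values(self):
        # alpha=2, beta=0, sigma=1, x0=1, dt=0.3
        m = ou_model(2.0, 0.0, 1.0)
        d = slice_density(m, AgePoint(1.0, 1.0), 1.3)
        mean, var = ou_closed_form(2.0, 0.0, 1.0, 1.0, 1.3, 1.0)
        assert d.mean == pytest.approx(mean, rel=1e-12)
        assert d.variance == pytest.approx(var, rel=1e-12)
        assert d.mean == pytest.approx(0.5488, abs=1e-4)
        assert d.variance == pytest.approx(0.1747, abs=1e-4)

    def test_time_backwards_raises(self, ou):
        with pytest.raises(ValueError, match="backwards"):
            slice_density(ou, AgePoint(5.0, 0.0), 4.0)

    def test_matches_numerical_quadrature(self, rng):
        """Mean/variance integrals agree with adaptive quadrature to 1e-10."""
        for _ in range(25):
            m = random_linear_sde(rng)
            p = m.params
            t0 = rng.uniform(0, 20)
            t1 = t0 + rng.uniform(0.01, 3)
            x0 = rng.uniform(-3, 3)
            d = slice_density(m, AgePoint(t0, x0), t1)
            poly = lambda u: p["a2"] + p["a3"] * u + p["a4"] * u**2 + p["a5"] * u**3
            mean_q = math.exp(p["a1"] * (t1 - t0)) * x0 + quad(
                lambda u: math.exp(p["a1"] * (t1 - u)) * poly(u), t0, t1, limit=200
            )[0]
            var_q = p["s"] ** 2 * quad(
                lambda u: math.exp(2 * p["a1"] * (t1 - u)), t0, t1
            )[0]
            assert d.mean == pytest.approx(mean_q, abs=1e-10, rel=1e-10)
            assert d.variance == pytest.approx(var_q, abs=1e-10, rel=1e-10)

    def test_matches_printed_cubic_transition_mean(self, rng):
        """Agreement with the literal printed closed form of the cubic-drift
        transition mean (transcribed symbol for symbol)."""

        def printed_mean(a1, a2, a3, a4, a5, t0, t1, x0):
            e0, e1 = math.exp(t0 * a1), math.exp(t1 * a1)
            inner = (
                e1 * x0 * a1**4
                - 6 * (e0 - e1) * a5
                + a1 * (-2 * (e0 - e1) * a4 - 6 * (-e1 * t0 + e0 * t1) * a5)
                + a1**2
                * (
                    (-e0 + e1) * a3
                    + 2 * e1 * t0 * a4
                    + 3 * e1 * t0**2 * a5
                    - e0 * t1 * (2 * a4 + 3 * t1 * a5)
                )
                + a1**3
                * (
                    (-e0 + e1) * a2
                    + e1 * t0 * a3
                    + e1 * t0**2 * a4
                    + e1 * t0**3 * a5
                    - e0 * t1 * (a3 + t1 * (a4 + t1 * a5))
                )
            )
            return math.exp(-t0 * a1) * inner / a1**4

        for _ in range(50):
            m = random_linear_sde(rng)
            p = m.params
            t0 = rng.uniform(0, 20)
            t1 = t0 + rng.uniform(0.1, 3)
            x0 = rng.uniform(-3, 3)
            d = slice_density(m, AgePoint(t0, x0), t1)
            ref = printed_mean(
                p["a1"], p["a2"], p["a3"], p["a4"], p["a5"], t0, t1, x0
            )
            assert d.mean == pytest.approx(ref, rel=1e-9, abs=1e-9)

    def test_polynomial_reduces_to_ou(self, rng):
        """With the cubic terms zeroed, the polynomial slice density equals
        the OU slice density under a1=-alpha, a2=alpha*beta, to 1e-12."""
        for _ in range(100):
            alpha = rng.uniform(0.2, 3.0)
            beta = rng.uniform(-2, 2)
            sigma = rng.uniform(0.2, 1.5)
            poly = SDEModelSpec(
                drift_order=0,
                mean_reversion=True,
                params={"a1": -alpha, "a2": alpha * beta, "s": sigma},
            )
            t0 = rng.uniform(0, 24)
            t1 = t0 + rng.uniform(0, 3)
            x0 = rng.uniform(-4, 3)
            d = slice_density(poly, AgePoint(t0, x0), t1)
            mean, var = ou_closed_form(alpha, beta, sigma, t0, t1, x0)
            assert abs(d.mean - mean) < 1e-12 * max(1, abs(mean))
            assert abs(d.variance - var) < 1e-12 * max(1, var)

    def test_chapman_kolmogorov(self, rng):
        """Composing t0->tm and tm->t1 reproduces t0->t1 to 1e-10."""
        for _ in range(100):
            m = random_linear_sde(rng)
            t0 = rng.uniform(0, 20)
            tm = t0 + rng.uniform(0, 2)
            t1 = tm + rng.uniform(0, 2)
            x0 = rng.uniform(-3, 3)
            d1 = slice_density(m, AgePoint(t0, x0), tm)
            d2 = slice_density(m, AgePoint(tm, d1.mean), t1)
            dfull = slice_density(m, AgePoint(t0, x0), t1)
            scale = math.exp(2 * m.params["a1"] * (t1 - tm))
            assert d2.mean == pytest.approx(dfull.mean, rel=1e-10, abs=1e-10)
            assert d2.variance + scale * d1.variance == pytest.approx(
                dfull.variance, rel=1e-10, abs=1e-10
            )

    def test_small_mean_reversion_continuity(self):
        """a1 = +/-1e-8 sits within 1e-6 of the exact a1=0 limit."""
        b = (0.3, -0.1, 0.02, -0.001)
        for a1 in (1e-8, -1e-8):
            m1, v1 = slice_mean_var(a1, b, 0.5, 2.0, 3.5, -1.0)
            m0, v0 = slice_mean_var(0.0, b, 0.5, 2.0, 3.5, -1.0)
            assert abs(float(m1) - float(m0)) < 1e-6
            assert abs(float(v1) - float(v0)) < 1e-6

    def test_variance_increases_with_elapsed_time(self, rng):
        for _ in range(20):
            m = random_linear_sde(rng)
            t0 = rng.uniform(0, 10)
            dts = np.sort(rng.uniform(0.01, 5, size=8))
            vs = [
                slice_density(m, AgePoint(t0, 0.0), t0 + dt).variance for dt in dts
            ]
            assert np.all(np.diff(vs) > 0)


class TestOUCovariance:
    def test_zero_at_the_start(self, ou):
        assert ou_covariance(ou, 1.0, 1.0, 1.0) == pytest.approx(0.0, abs=1e-15)

    def test_symmetric_in_the_two_ages(self, ou):
        a = ou_covariance(ou, 0.0, 0.5, 1.0)
        b = ou_covariance(ou, 0.0, 1.0, 0.5)
        assert a == pytest.approx(b, rel=1e-14)

    def test_requires_ou_form(self, cubic):
        with pytest.raises(ValueError, match="OU"):
            ou_covariance(cubic, 0.0, 0.5, 1.0)

    def test_matches_exact_simulation(self):
        """Empirical covariance of exactly sampled path pairs within 3 MC SE."""
        alpha, sigma, t0, s_t, t_t = 1.0, 1.0, 0.0, 0.5, 1.0
        m = ou_model(alpha, 0.0, sigma)
        n = 400_000
        gen = np.random.default_rng(5)
        x0 = np.zeros(n)
        ms, vs = slice_mean_var(-alpha, (0, 0, 0, 0), sigma, t0, s_t, x0)
        xs = ms + np.sqrt(vs) * gen.standard_normal(n)
        mt, vt = slice_mean_var(-alpha, (0, 0, 0, 0), sigma, s_t, t_t, xs)
        xt = mt + np.sqrt(vt) * gen.standard_normal(n)
        emp = float(np.mean(xs * xt) - np.mean(xs) * np.mean(xt))
        # MC standard error of a covariance estimate
        se = float(np.std(xs * xt) / math.sqrt(n))
        ref = ou_covariance(m, t0, s_t, t_t)
        assert abs(emp - ref) < 3 * se


class TestModelSpec:
    def test_diffusion_must_be_positive(self):
        with pytest.raises(ValueError, match="s must be > 0"):
            SDEModelSpec(drift_order=0, mean_reversion=False, params={"a2": 0.0, "s": 0.0})

    def test_no_mean_reversion_forbids_a1(self):
        with pytest.raises(ValueError):
            SDEModelSpec(
                drift_order=0, mean_reversion=False, params={"a1": -1.0, "s": 1.0}
            )

    def test_site_offset_keeps_diffusion_positive(self):
        m = ou_model(1.0, 0.0, 0.5, site_offsets={"s": {"a": -1.0, "b": 0.7}})
        assert m.params_for_site("a")["s"] == pytest.approx(0.5 * math.exp(-1.0))
        assert m.params_for_site("b")["s"] == pytest.approx(0.5 * math.exp(0.7))

    def test_drift_site_offset_is_additive(self):
        m = ou_model(1.0, 0.0, 0.5, site_offsets={"a2": {"a": 0.0, "b": 0.3}})
        assert m.params_for_site("b")["a2"] == pytest.approx(0.3)

    def test_yaml_round_trip(self, tmp_path, cubic):
        m = SDEModelSpec(
            drift_order=cubic.drift_order,
            mean_reversion=True,
            params=dict(cubic.params),
            site_offsets={"a2": {"haydom": 0.0, "venda": 0.15}, "s": {"haydom": 0.0, "venda": -0.1}},
            random_effect_names=("a2", "s"),
        )
        path = tmp_path / "model.yaml"
        m.to_yaml(path)
        back = SDEModelSpec.from_yaml(path)
        assert back == m

    def test_ou_reparameterization_round_trip(self):
        m = ou_model(1.7, -0.4, 0.9)
        alpha, beta, sigma = m.ou_params()
        assert (alpha, beta, sigma) == pytest.approx((1.7, -0.4, 0.9))
        assert m.params["a1"] == pytest.approx(-1.7)
        assert m.params["a2"] == pytest.approx(1.7 * -0.4)
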