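"""Transition likelihood, fixed-effects MLE and mixed-effects estimation."""

import math

import numpy as np
import pytest
from scipy.stats import norm

from growthsde import (
    AgePoint,
    CohortData,
    CohortDesign,
    FitOptions,
    SDEModelSpec,
    Trajectory,
    cohort_negloglik,
    fit_linear_baseline,
    fit_mixed_sde,
    fit_mle,
    ou_model,
    simulate_cohort,
    slice_density,
    trajectory_negloglik,
)

FAST = FitOptions(n_restarts=2, seed=0)


def _traj(pairs, child="c", site=None):
    return Trajectory(child, site, tuple(AgePoint(a, v) for a, v in pairs))


def oracle_negloglik(model, tr):
    """Independent composition: slice density + Gaussian log-pdf."""
    total = 0.0
    for p0, p1 in zip(tr.points[:-1], tr.points[1:]):
        d = slice_density(model, p0, p1.age, site=tr.site)
        total -= norm.logpdf(p1.value, loc=d.mean, scale=math.sqrt(d.variance))
    return total


class TestTrajectoryNegloglik:
    def test_two_point_ou_value(self):
        """OU alpha=1, beta=0, sigma=1 on [(0,0),(1,0.2)]: the transition
        variance is (1-e^-2)/2 and the negative log-likelihood ~ 0.5460."""
        m = ou_model(1.0, 0.0, 1.0)
        tr = _traj([(0.0, 0.0), (1.0, 0.2)])
        var = (1 - math.exp(-2.0)) / 2.0
        expected = 0.5 * math.log(2 * math.pi * var) + 0.2**2 / (2 * var)
        val = trajectory_negloglik(m, tr)
        assert val == pytest.approx(expected, rel=1e-12)
        assert val == pytest.approx(0.5460, abs=1e-4)

    def test_additivity_over_transitions(self, ou, rng):
        pts = [(i * 1.0, rng.normal()) for i in range(6)]
        tr = _traj(pts)
        total = trajectory_negloglik(ou, tr)
        parts = sum(
            trajectory_negloglik(ou, _traj([pts[i], pts[i + 1]]))
            for i in range(5)
        )
        assert total == pytest.approx(parts, rel=1e-12)

    def test_duplicating_a_trajectory_doubles_the_cohort_likelihood(self, ou, rng):
        pts = [(i * 1.0, rng.normal()) for i in range(5)]
        one = cohort_negloglik(ou, [_traj(pts, "a")])
        two = cohort_negloglik(ou, [_traj(pts, "a"), _traj(pts, "b")])
        assert two == pytest.approx(2 * one, rel=1e-12)

    def test_matches_independent_gaussian_composition(self, rng):
        """100 random trajectories: equality with the slice-density +
        Gaussian-log-pdf oracle to 1e-10."""
        from conftest import random_linear_sde

        for _ in range(100):
            m = random_linear_sde(rng)
            ages = np.cumsum(rng.uniform(0.2, 2.0, size=rng.integers(2, 8)))
            vals = rng.normal(size=len(ages))
            tr = _traj(list(zip(ages, vals)))
            ours = trajectory_negloglik(m, tr)
            assert ours == pytest.approx(oracle_negloglik(m, tr), rel=1e-10, abs=1e-10)

    def test_zero_variance_mismatch_is_infinite_with_warning(self, ou):
        tr = _traj([(0.0, 0.0), (1.0, 5.0)])
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            val = trajectory_negloglik(ou, tr, params={"s": 0.0})
        assert val == math.inf

    def test_single_point_trajectory_rejected(self, ou):
        with pytest.raises(ValueError, match="2 points"):
            trajectory_negloglik(ou, _traj([(0.0, 0.0)]))


class TestFitMLE:
    def test_near_noiseless_data_recovers_drift(self):
        """With sigma -> 0 the data follow the deterministic mean path and
        the drift parameters are recovered to optimizer tolerance."""
        gen = SDEModelSpec(
            drift_order=1,
            mean_reversion=True,
            params={"a1": -0.8, "a2": 0.3, "a3": -0.05, "s": 1e-4},
        )
        design = CohortDesign(
            n_children_per_site=5, sites=("a",), p_visit_missing=0.0, seed=2,
            initial_mean=0.5, initial_sd=0.2,
        )
        cohort = simulate_cohort(gen, design)
        fit = fit_mle(gen, cohort, options=FAST, parameterization="natural")
        assert fit.converged
        assert fit.estimates["a1"] == pytest.approx(-0.8, abs=0.02)
        assert fit.estimates["a2"] == pytest.approx(0.3, abs=0.02)
        assert fit.estimates["a3"] == pytest.approx(-0.05, abs=0.01)

    def test_ou_recovery_within_wald_bands(self, small_cohort):
        fit = fit_mle(ou_model(1.0, 0.0, 1.0), small_cohort, options=FAST,
                      parameterization="ou")
        truth = {"alpha": 1.2, "beta": -0.8, "sigma": 0.6}
        assert fit.converged
        for name, tv in truth.items():
            z = abs(fit.estimates[name] - tv) / fit.standard_errors[name]
            assert z < 4.0, f"{name}: |z|={z:.2f}"

    def test_information_criteria_arithmetic(self, small_cohort):
        fit = fit_mle(ou_model(1.0, 0.0, 1.0), small_cohort, options=FAST)
        assert fit.aic == pytest.approx(2 * fit.n_params - 2 * fit.loglik)
        assert fit.bic == pytest.approx(
            fit.n_params * math.log(fit.n_obs) - 2 * fit.loglik
        )

    def test_time_rescaling_leaves_max_likelihood_unchanged(self, small_cohort):
        """Rescaling ages by c maps OU(alpha, sigma^2) to
        (alpha/c, sigma^2/c) with identical transition densities, so the
        maximized likelihood is invariant."""
        c = 2.0
        scaled = [
            Trajectory(tr.child_id, tr.site,
                       tuple(AgePoint(p.age * c, p.value) for p in tr.points))
            for tr in small_cohort
        ]
        f1 = fit_mle(ou_model(1.0, 0.0, 1.0), small_cohort, options=FAST,
                     parameterization="ou")
        f2 = fit_mle(ou_model(1.0, 0.0, 1.0), scaled, options=FAST,
                     parameterization="ou")
        assert f2.loglik == pytest.approx(f1.loglik, abs=1e-4)
        assert f2.estimates["alpha"] == pytest.approx(f1.estimates["alpha"] / c, rel=1e-3)
        assert f2.estimates["sigma"] ** 2 == pytest.approx(
            f1.estimates["sigma"] ** 2 / c, rel=1e-3
        )

    def test_site_offsets_recovered(self):
        gen = ou_model(1.0, -0.5, 0.5)
        gen_b = SDEModelSpec(
            drift_order=0, mean_reversion=True,
            params={"a1": -1.0, "a2": -0.5 + 0.4, "s": 0.5},
        )
        d = dict(n_children_per_site=40, p_visit_missing=0.0, initial_mean=-0.5,
                 initial_sd=0.5)
        ca = simulate_cohort(gen, CohortDesign(sites=("a",), seed=4, **d))
        cb = simulate_cohort(gen_b, CohortDesign(sites=("b",), seed=5, **d))
        template = SDEModelSpec(
            drift_order=0, mean_reversion=True,
            params={"a1": -1.0, "a2": -0.5, "s": 0.5},
            site_offsets={"a2": {"a": 0.0, "b": 0.0}},
        )
        fit = fit_mle(template, ca + cb, options=FAST, parameterization="natural")
        assert fit.converged
        assert fit.estimates["a2@b"] == pytest.approx(0.4, abs=3 * fit.standard_errors["a2@b"])


class TestLinearBaselines:
    def test_transition_baseline_on_noise_free_linear_growth(self):
        trs = [
            _traj([(t, 0.1 * t + c) for t in range(10)], f"c{c}")
            for c in (0, 1)
        ]
        fit = fit_linear_baseline(trs, kind="transition")
        assert fit.estimates["b"] == pytest.approx(0.1, abs=1e-10)
        assert fit.estimates["sigma"] == pytest.approx(0.0, abs=1e-8)
        assert fit.n_params == 2

    def test_global_regression_equals_closed_form_ols(self, small_cohort):
        fit = fit_linear_baseline(small_cohort, kind="global")
        ages = np.concatenate([tr.ages for tr in small_cohort])
        vals = np.concatenate([tr.values for tr in small_cohort])
        X = np.column_stack([np.ones_like(ages), ages])
        beta = np.linalg.solve(X.T @ X, X.T @ vals)
        assert fit.estimates["c0"] == pytest.approx(beta[0], rel=1e-10)
        assert fit.estimates["c1"] == pytest.approx(beta[1], rel=1e-10)
        sig2 = np.mean((vals - X @ beta) ** 2)
        assert fit.loglik == pytest.approx(
            -0.5 * len(vals) * (math.log(2 * math.pi * sig2) + 1), rel=1e-12
        )

    def test_ou_beats_both_baselines_on_mean_reverting_data(self, small_cohort):
        ou_fit = fit_mle(ou_model(1.0, 0.0, 1.0), small_cohort, options=FAST)
        for kind in ("transition", "global"):
            assert ou_fit.aic < fit_linear_baseline(small_cohort, kind=kind).aic


@pytest.fixture(scope="module")
def re_cohort():
    # random long-term mean per child, sd 0.5 (on beta = a2/alpha)
    gen = ou_model(1.2, -0.8, 0.6, random_effect_names=("a2",))
    design = CohortDesign(
        n_children_per_site=25, sites=("a", "b"), p_visit_missing=0.0,
        seed=31, random_effects_cov=np.array([[(1.2 * 0.5) ** 2]]),
        initial_mean=-0.8, initial_sd=0.8,
    )
    return simulate_cohort(gen, design)


class TestMixedSDE:

    def test_zero_covariance_constraint_reproduces_fixed_fit(self, re_cohort):
        fixed = fit_mle(ou_model(1.0, 0.0, 1.0), re_cohort, options=FAST,
                        parameterization="ou")
        mixed = fit_mixed_sde(
            ou_model(1.0, 0.0, 1.0), re_cohort, ("beta",),
            re_cov_fixed=np.zeros((1, 1)), options=FAST, parameterization="ou",
        )
        for k in ("alpha", "beta", "sigma"):
            assert mixed.estimates[k] == pytest.approx(fixed.estimates[k], abs=1e-6)
        assert mixed.loglik == pytest.approx(fixed.loglik, abs=1e-6)
        assert all(v["beta"] == 0.0 for v in mixed.empirical_bayes.values())

    def test_random_mean_sd_recovered(self, re_cohort):
        fit = fit_mixed_sde(
            ou_model(1.0, 0.0, 1.0), re_cohort, ("beta",),
            options=FitOptions(n_restarts=1, seed=0), parameterization="ou",
        )
        assert fit.converged
        sd_hat = fit.estimates["sd(beta)"]
        se = fit.standard_errors["sd(beta)"]
        assert abs(sd_hat - 0.5) < 3 * se

    def test_quadrature_node_count_insensitive(self, re_cohort):
        """5-node vs 21-node adaptive Gauss–Hermite marginal log-likelihood:
        near-exact for a random effect entering the transition mean (the
        integrand is then Gaussian in b), and accurate per child for the
        harder log-diffusion random effect."""
        from growthsde.fit import CohortData, _MixedLikelihood, _make_family

        data = CohortData(re_cohort[:20])
        fam = _make_family(ou_model(1.2, -0.8, 0.6), data, "ou")
        theta = np.array([math.log(1.2), -0.8, math.log(0.6)])
        L = np.array([[0.3]])
        for re_name, tol in (("beta", 1e-3), ("sigma", 1e-3 * data.n_children)):
            vals = {}
            for nodes in (5, 21):
                mix = _MixedLikelihood(
                    fam, data, (re_name,), "diagonal", FitOptions(agh_nodes=nodes)
                )
                vals[nodes] = mix.marginal_negloglik_L(theta, L)
            assert vals[5] == pytest.approx(vals[21], abs=tol), re_name

    def test_empirical_bayes_shrinks_with_less_data(self, re_cohort):
        """Truncating each child to 3 visits pulls the empirical-Bayes
        modes toward zero (paired comparison on the same children, holding
        the fitted parameters fixed)."""
        from growthsde.fit import empirical_bayes_modes

        fit = fit_mixed_sde(
            ou_model(1.2, -0.8, 0.6), re_cohort, ("beta",),
            re_cov_fixed=np.array([[0.25]]),
            options=FitOptions(n_restarts=1), parameterization="ou",
        )
        short = [
            Trajectory(tr.child_id, tr.site, tr.points[:3]) for tr in re_cohort
        ]
        eb_short = empirical_bayes_modes(fit, short)
        b_full = np.array([fit.empirical_bayes[tr.child_id]["beta"] for tr in re_cohort])
        b_short = np.array([eb_short[tr.child_id]["beta"] for tr in re_cohort])
        # the population of modes contracts toward the prior mean 0
        assert np.mean(np.abs(b_short)) < np.mean(np.abs(b_full))
        assert np.var(b_short) < np.var(b_full)

    def test_requires_known_random_effect_name(self, re_cohort):
        with pytest.raises(ValueError, match="random effect"):
            fit_mixed_sde(ou_model(1, 0, 1), re_cohort, ("gamma",), options=FAST)
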