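"""Tests for MAP fitting and evidence approximation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from confrl import (
    MapLaplaceFitter,
    ModelSpec,
    ParamSet,
    fit_map,
    laplace_log_evidence,
    session_log_likelihood,
    simulate_agent,
)
from confrl.inversion import PriorSpec, to_native, to_transformed

from conftest import make_manual_session


class TestLogLikelihood:
    def test_five_trial_hand_unrolled_product(self):
        """exp(LL) equals the explicitly unrolled per-trial product for a
        valence-coded agent without confidence modulation."""
        session = make_manual_session(
            ["risky", "risky", "safe", "risky", "safe"],
            [1.0, -1.0, 0.1, 1.0, -0.1],
        )
        alpha, beta = 0.3, 0.8
        theta = ParamSet(alpha0=alpha, beta0=beta)
        # unrolled: Q starts at 0, delta rule on outcome sign
        def soft(q):
            return 1.0 / (1.0 + np.exp(-q / beta))
        q = 0.0
        p1 = soft(q)            # risky chosen
        q += alpha * (1 - q)
        p2 = soft(q)            # risky chosen
        q += alpha * (-1 - q)
        p3 = 1 - soft(q)        # safe chosen
        q += alpha * (1 - q)
        p4 = soft(q)            # risky chosen
        q += alpha * (1 - q)
        p5 = 1 - soft(q)        # safe chosen
        expected = p1 * p2 * p3 * p4 * p5
        ll = session_log_likelihood(session, ModelSpec("valence"), theta)
        assert np.exp(ll) == pytest.approx(expected, abs=1e-12)

    def test_infinite_temperature_limit_is_random_choice(self, best_spec):
        theta = ParamSet(alpha0=0.5, beta0=1e8)
        session, _ = simulate_agent(ModelSpec("money"), theta, seed=0)
        ll = session_log_likelihood(session, ModelSpec("money"), theta)
        assert ll == pytest.approx(240 * np.log(0.5), abs=1e-4)

    def test_zero_kappa_hierarchical_equals_flat_twin(self):
        """With kappa = 0 the meta-level is inert: likelihood and value
        trajectory match the plain RL twin trial for trial."""
        from confrl.inversion import compute_trajectory

        flat = ModelSpec("coupled")
        hier = ModelSpec("coupled", "optimality", "both_shared")
        th_flat = ParamSet(alpha0=0.4, beta0=0.9)
        th_hier = ParamSet(alpha0=0.4, beta0=0.9, C0=0.3, gamma=0.2,
                           kappa=0.0)
        session, _ = simulate_agent(flat, th_flat, seed=4)
        ll_flat = session_log_likelihood(session, flat, th_flat)
        ll_hier = session_log_likelihood(session, hier, th_hier)
        assert ll_hier == pytest.approx(ll_flat, abs=1e-12)
        t_flat = compute_trajectory(session, flat, th_flat)
        t_hier = compute_trajectory(session, hier, th_hier)
        np.testing.assert_allclose(t_hier.q_a, t_flat.q_a, atol=1e-14)
        np.testing.assert_allclose(t_hier.p_choice, t_flat.p_choice,
                                   atol=1e-14)

    def test_true_parameters_beat_perturbed(self, best_spec, best_theta):
        """Monte-Carlo self-consistency: the generating parameters dominate
        a perturbed set in the large majority of simulated sessions."""
        perturbed = ParamSet(alpha0=0.3, beta0=1.2, C0=0.5, gamma=0.15,
                             kappa=1.2)
        wins = 0
        n = 200
        for seed in range(n):
            s, _ = simulate_agent(best_spec, best_theta, seed=seed)
            wins += (
                session_log_likelihood(s, best_spec, best_theta)
                > session_log_likelihood(s, best_spec, perturbed)
            )
        assert wins / n >= 0.95


class TestTransforms:
    def test_round_trip(self):
        for name, v in [("alpha0", 0.37), ("beta0", 2.2), ("gamma", 0.9),
                        ("kappa", 0.01), ("C0", 0.5)]:
            assert to_native(name, to_transformed(name, v)) == \
                pytest.approx(v)

    def test_priors_validated(self):
        spec = ModelSpec("money")
        with pytest.raises(ValueError, match="missing"):
            PriorSpec(mean={"alpha0": 0}, var={"alpha0": 1}).validate_for(
                spec
            )
        bad = PriorSpec(mean={"alpha0": 0, "beta0": 0},
                        var={"alpha0": 1, "beta0": -1})
        with pytest.raises(ValueError, match="positive"):
            bad.validate_for(spec)


class TestLaplaceEvidence:
    def test_conjugate_gaussian_closed_form(self):
        """On a Gaussian likelihood x Gaussian prior the Laplace value is
        exact: compare with the analytic log marginal."""
        rng = np.random.default_rng(3)
        sigma, tau, n = 1.3, 2.0, 12
        y = rng.normal(0.7, sigma, size=n)

        def log_joint(x):
            th = x[0]
            ll = np.sum(sps.norm.logpdf(y, th, sigma))
            return ll + sps.norm.logpdf(th, 0.0, tau)

        post_var = 1.0 / (n / sigma**2 + 1.0 / tau**2)
        x_map = np.array([post_var * np.sum(y) / sigma**2])
        le, info = laplace_log_evidence(log_joint, x_map)
        cov = sigma**2 * np.eye(n) + tau**2 * np.ones((n, n))
        exact = sps.multivariate_normal.logpdf(y, np.zeros(n), cov)
        assert le == pytest.approx(exact, abs=1e-6)
        assert not info["jittered"]

    def test_occam_penalty_on_nested_models(self):
        """Data from plain RL: the 5-parameter hierarchical extension has
        lower evidence in most replicates."""
        flat = ModelSpec("coupled")
        hier = ModelSpec("coupled", "optimality", "both_shared")
        theta = ParamSet(alpha0=0.45, beta0=0.8)
        wins = 0
        n = 40
        for seed in range(n):
            s, _ = simulate_agent(flat, theta, seed=300 + seed)
            le_flat = fit_map(s, flat, n_restarts=2, seed=0).log_evidence
            le_hier = fit_map(s, hier, n_restarts=2, seed=0).log_evidence
            wins += le_flat > le_hier
        assert wins / n >= 0.8


class TestFitMap:
    def test_reproducible_given_seed(self, best_spec, best_theta):
        s, _ = simulate_agent(best_spec, best_theta, seed=9)
        f1 = fit_map(s, best_spec, n_restarts=3, seed=123)
        f2 = fit_map(s, best_spec, n_restarts=3, seed=123)
        np.testing.assert_array_equal(f1.x_map, f2.x_map)
        assert f1.log_evidence == f2.log_evidence

    def test_evidence_penalised_below_best_fit(self, best_spec, best_theta):
        # evidence trades accuracy against complexity: it sits below the
        # maximum attainable log-likelihood by the prior + volume penalty
        s, _ = simulate_agent(best_spec, best_theta, seed=9)
        fr = fit_map(s, best_spec, n_restarts=3, seed=0)
        assert fr.log_evidence < fr.log_likelihood
        assert np.isfinite(fr.hessian_logdet)

    def test_degenerate_all_identical_choices(self):
        session = make_manual_session(["risky"] * 60, [1.0] * 60)
        fr = fit_map(session, ModelSpec("valence"), n_restarts=2, seed=0)
        assert np.isfinite(fr.log_evidence)
        # prior regularization keeps the temperature estimate finite
        assert 0 < fr.theta_map.beta0 < 50

    def test_restart_validation(self, example_session, best_spec):
        with pytest.raises(ValueError):
            fit_map(example_session[0], best_spec, n_restarts=0)


class TestEstimatorInterface:
    def test_fitter_follows_sklearn_conventions(self, example_session):
        session, _ = example_session
        est = MapLaplaceFitter("coupled.flat", n_restarts=2, random_state=0)
        assert est.get_params()["n_restarts"] == 2
        est.set_params(n_restarts=3)
        est.fit(session)
        assert hasattr(est, "theta_map_")
        assert est.log_evidence_ < 0
        assert est.score(session) == pytest.approx(est.log_likelihood_)
        clone_params = est.get_params()
        assert clone_params["spec"] == "coupled.flat"
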