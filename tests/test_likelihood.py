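"""Conditional intensities, quadrature marginalisation, and the
mover-stayer mixture."""

import copy

import numpy as np
import pytest
from scipy.special import logsumexp

import jointmsm as jm
from jointmsm.likelihood import (QuadratureRule, conditional_intensities,
                                 joint_interval_logprob)
from jointmsm.markov import SIX_STAYER, build_generator, expm_mover4, get_space
from conftest import reduced_config, reduced_theta, five_state_config, five_state_theta

Z0 = {"ama": 0.0, "sex": 0.0, "attained_damaged_count": 0.0, "opposite_damaged": 0.0}


class TestConditionalIntensities:
    def test_baseline_case(self, six_config, six_theta):
        lam = conditional_intensities(six_theta, Z0, 0.0, 0.0, "mover", six_config)
        assert lam[(1, 2)] == pytest.approx(np.exp(six_theta.log_lam0["AbarA"]))
        assert lam[(1, 3)] == pytest.approx(np.exp(six_theta.log_lam0["DbarD"]))

    def test_proportional_stayer_and_damage_effects(self, six_config, six_theta):
        mover = conditional_intensities(six_theta, Z0, 0.3, -0.2, "mover", six_config)
        stay = conditional_intensities(six_theta, Z0, 0.3, -0.2, "stayer", six_config)
        assert stay[(5, 6)] / mover[(1, 2)] == pytest.approx(
            np.exp(six_theta.beta_stayer["AbarA"]))
        assert mover[(3, 4)] / mover[(1, 2)] == pytest.approx(
            np.exp(six_theta.beta_damaged["AbarA"]))
        assert mover[(2, 4)] / mover[(1, 3)] == pytest.approx(
            np.exp(six_theta.beta_active_DbarD))

    def test_random_effect_loading(self, six_config, six_theta):
        base = conditional_intensities(six_theta, Z0, 0.0, 0.0, "mover", six_config)
        moved = conditional_intensities(six_theta, Z0, 1.0, 0.0, "mover", six_config)
        assert moved[(1, 2)] / base[(1, 2)] == pytest.approx(np.e)
        assert moved[(2, 1)] / base[(2, 1)] == pytest.approx(np.exp(six_theta.alpha))
        assert moved[(1, 3)] == pytest.approx(base[(1, 3)])  # v unchanged

    def test_five_state_jump_probability_odds(self):
        cfg = five_state_config()
        th = five_state_theta(cfg)
        z = {"ama": 0.0, "opposite_damaged": 0.0}
        v = 0.7
        lam = conditional_intensities(th, z, 0.0, v, "mover", cfg)
        odds = np.exp(th.log_odds0["AbarD"] + v)
        p13 = odds / (1 + odds)
        mu1 = np.exp(th.log_mu0["Abar"])
        assert lam[(1, 3)] == pytest.approx(p13 / mu1)
        assert lam[(1, 2)] == pytest.approx((1 - p13) / mu1)

    def test_nonfinite_covariate_reported(self, six_config, six_theta):
        z = dict(Z0, ama=np.nan)
        with pytest.raises(ValueError, match="ama"):
            conditional_intensities(six_theta, z, 0.0, 0.0, "mover", six_config)


class TestJointIntervalLogprob:
    def test_short_interval_same_state_near_zero(self):
        Q = build_generator({(5, 6): 0.8, (6, 5): 1.1}, SIX_STAYER)
        assert joint_interval_logprob(5, 5, 1e-9, Q, SIX_STAYER) == pytest.approx(0.0, abs=1e-8)

    def test_stayer_damaged_state_is_minus_inf(self):
        Q = build_generator({(5, 6): 0.8}, SIX_STAYER)
        assert joint_interval_logprob(5, 3, 1.0, Q, SIX_STAYER) == -np.inf

    def test_frozen_chain(self):
        space = get_space("six_state", "mover")
        Q = build_generator({}, space)
        assert joint_interval_logprob(1, 1, 2.0, Q, space) == 0.0
        assert joint_interval_logprob(1, 2, 2.0, Q, space) == -np.inf


class TestQuadrature:
    def test_weights_normalised(self):
        for n in (1, 5, 15, 30):
            rule = QuadratureRule.gauss_hermite(n)
            assert rule.weights.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.all(rule.weights > 0)

    def test_single_node_sits_at_mean(self):
        rule = QuadratureRule.gauss_hermite(1)
        assert rule.nodes[0] == pytest.approx(0.0, abs=1e-15)

    def test_invalid_node_count(self):
        with pytest.raises(ValueError):
            QuadratureRule.gauss_hermite(0)

    def test_one_node_equals_conditional_at_zero(self, small_evaluator, six_theta):
        one = small_evaluator.total_loglik(six_theta, rule=QuadratureRule.gauss_hermite(1))
        cond = small_evaluator.total_loglik(six_theta, fixed_uv=(0.0, 0.0))
        assert one == pytest.approx(cond, abs=1e-10)

    def test_vanishing_variance_equals_fixed_effects(self, small_dataset, six_config, six_theta):
        th = copy.deepcopy(six_theta)
        th.sigma2_u = th.sigma2_v = 1e-12
        ev = jm.LikelihoodEvaluator(small_dataset, six_config)
        assert ev.total_loglik(th) == pytest.approx(
            ev.total_loglik(th, fixed_uv=(0.0, 0.0)), abs=1e-6)

    def test_node_doubling_converges(self, small_dataset, six_theta):
        """Under moderate unobserved heterogeneity the Gauss-Hermite value
        sequence is Cauchy convergent; 28 joints sharing a frailty make the
        integrand sharper as the variance grows, so convergence is assessed
        where the rule is within reach."""
        th = copy.deepcopy(six_theta)
        th.sigma2_u = th.sigma2_v = 0.5
        ev = jm.LikelihoodEvaluator(small_dataset, reduced_config())
        lls = [ev.total_loglik(th, rule=QuadratureRule.gauss_hermite(n))
               for n in (5, 10, 20, 40)]
        deltas = np.abs(np.diff(lls))
        assert deltas[2] < deltas[1] < deltas[0]
        assert deltas[-1] < 1e-2

    def test_marginal_matches_monte_carlo_single_joint(self, six_config, six_theta):
        """GH quadrature vs brute-force MC integration of one joint's
        transition probability over one interval."""
        rng = np.random.default_rng(99)
        z = {"ama": 0.3, "sex": 1.0, "attained_damaged_count": 2.0, "opposite_damaged": 1.0}
        dt, sfrom, sto = 0.8, 0, 1
        rule = QuadratureRule.gauss_hermite(15)
        su, sv, rho = np.sqrt(six_theta.sigma2_u), np.sqrt(six_theta.sigma2_v), six_theta.rho
        # quadrature with the conditional factorisation phi(v|u) phi(u)
        quad = 0.0
        for xu, wu in zip(rule.nodes, rule.weights):
            u = su * xu
            for xv, wv in zip(rule.nodes, rule.weights):
                v = rho * sv * xu + sv * np.sqrt(1 - rho**2) * xv
                lam = conditional_intensities(six_theta, z, u, v, "mover", six_config)
                P = expm_mover4(lam[(1, 2)], lam[(2, 1)], lam[(1, 3)], lam[(2, 4)],
                                lam[(3, 4)], lam[(4, 3)], dt)
                quad += wu * wv * P[sfrom, sto]
        n = 200_000
        cov = np.array([[su**2, rho * su * sv], [rho * su * sv, sv**2]])
        draws = rng.multivariate_normal([0, 0], cov, size=n)
        e12 = six_theta.log_lam0["AbarA"] + 0.3 * 2.0 + 1.0 * (-0.7)
        e21 = six_theta.log_lam0["AAbar"] + 0.3 * (-0.5)
        e13 = six_theta.log_lam0["DbarD"] + 0.3 * 2.0 + 2.0 * 0.1 + 1.0 * 0.8
        l12 = np.exp(e12 + draws[:, 0])
        l21 = np.exp(e21 + six_theta.alpha * draws[:, 0])
        l13 = np.exp(e13 + draws[:, 1])
        P = expm_mover4(l12, l21, l13, l13 * np.exp(six_theta.beta_active_DbarD),
                        l12 * np.exp(six_theta.beta_damaged["AbarA"]),
                        l21 * np.exp(six_theta.beta_damaged["AAbar"]), dt)
        vals = P[:, sfrom, sto]
        mc, se = vals.mean(), vals.std(ddof=1) / np.sqrt(n)
        assert abs(quad - mc) < 3 * se


class TestMixture:
    def test_pi_zero_collapses_to_mover(self, small_evaluator, six_theta):
        th = copy.deepcopy(six_theta)
        th.pi = 0.0
        Lm, _ = small_evaluator.class_logliks(th)
        assert np.allclose(small_evaluator.patient_logliks(th), Lm)

    def test_cstar_one_exact_form(self, small_evaluator, six_theta):
        ll = small_evaluator.patient_logliks(six_theta)
        Lm, _ = small_evaluator.class_logliks(six_theta)
        damaged = small_evaluator._c_star == 1
        assert damaged.any()
        assert np.allclose(ll[damaged], np.log1p(-six_theta.pi) + Lm[damaged])

    def test_mixture_bounds_for_damage_free(self, small_evaluator, six_theta):
        Lm, Ls = small_evaluator.class_logliks(six_theta)
        ll = small_evaluator.patient_logliks(six_theta)
        free = small_evaluator._c_star == 0
        lo = np.minimum(Lm[free], Ls[free])
        hi = np.maximum(Lm[free], Ls[free])
        assert np.all(ll[free] >= lo - 1e-12)
        assert np.all(ll[free] <= hi + 1e-12)  # weights sum to < 1

    def test_stayer_equals_mover_margin_when_effects_vanish(self, small_dataset):
        """With stayer effects zero and the damage intensity switched off the
        mover's activity chain marginalises to the stayer chain exactly."""
        cfg = reduced_config()
        th = reduced_theta(cfg)
        th.beta_stayer = {"AbarA": 0.0, "AAbar": 0.0}
        th.log_lam0["DbarD"] = -40.0
        ev = jm.LikelihoodEvaluator(small_dataset, cfg)
        Lm, Ls = ev.class_logliks(th)
        free = ev._c_star == 0
        assert np.allclose(Lm[free], Ls[free], atol=1e-8)

    def test_total_is_sum_and_order_invariant(self, small_dataset, six_config, six_theta):
        ev = jm.LikelihoodEvaluator(small_dataset, six_config)
        total = ev.total_loglik(six_theta)
        assert total == pytest.approx(ev.patient_logliks(six_theta).sum())
        # reverse patient order
        ds2 = jm.PanelDataset(small_dataset.joints.iloc[::-1].reset_index(drop=True),
                              small_dataset.patients.iloc[::-1].reset_index(drop=True),
                              small_dataset.layout)
        ev2 = jm.LikelihoodEvaluator(ds2, six_config)
        assert ev2.total_loglik(six_theta) == pytest.approx(total, abs=1e-8)

    def test_duplicating_patients_doubles_loglik(self, small_dataset, six_config, six_theta):
        j2 = small_dataset.joints.copy()
        j2["patient_id"] = j2["patient_id"] + 1000
        p2 = small_dataset.patients.copy()
        p2["patient_id"] = p2["patient_id"] + 1000
        import pandas as pd
        ds2 = jm.PanelDataset(pd.concat([small_dataset.joints, j2]),
                              pd.concat([small_dataset.patients, p2]),
                              small_dataset.layout)
        ev2 = jm.LikelihoodEvaluator(ds2, six_config)
        single = jm.LikelihoodEvaluator(small_dataset, six_config).total_loglik(six_theta)
        assert ev2.total_loglik(six_theta) == pytest.approx(2 * single, rel=1e-10)

    def test_joint_relabelling_invariance(self, small_dataset, six_config, six_theta):
        """Swapping the two joints of a contralateral pair (same type, mirrored
        pairing) leaves the marginal likelihood unchanged."""
        j = small_dataset.joints.copy()
        swap = {3: 17, 17: 3}
        j["joint_id"] = j["joint_id"].map(lambda x: swap.get(x, x))
        ds2 = jm.PanelDataset(j, small_dataset.patients, small_dataset.layout)
        base = jm.LikelihoodEvaluator(small_dataset, six_config).total_loglik(six_theta)
        assert jm.LikelihoodEvaluator(ds2, six_config).total_loglik(six_theta) == \
            pytest.approx(base, abs=1e-8)


class TestRandomEffectStructures:
    def test_single_interval_patients_agree(self, six_config, six_theta):
        """With one usable interval per patient, observation-level and
        patient-level random effects are the same model."""
        sim = jm.SimConfig(n_patients=10, theta=six_theta, config=six_config,
                           seed=31, visit_range=(3, 3))
        ds = jm.simulate_cohort(sim).dataset
        ev_obs = jm.LikelihoodEvaluator(ds, reduced_config(re_structure="observation"))
        ev_pat = jm.LikelihoodEvaluator(ds, reduced_config(re_structure="patient", quad_nodes=7))
        assert ev_obs.total_loglik(six_theta) == pytest.approx(
            ev_pat.total_loglik(six_theta), abs=1e-8)

    def test_multi_interval_patients_differ(self, small_dataset, six_theta):
        ev_obs = jm.LikelihoodEvaluator(small_dataset, reduced_config())
        ev_pat = jm.LikelihoodEvaluator(small_dataset,
                                        reduced_config(re_structure="patient", quad_nodes=7))
        assert abs(ev_obs.total_loglik(six_theta) - ev_pat.total_loglik(six_theta)) > 1.0

    def test_interval_marginal_factor_positive_and_composes(self, small_evaluator, six_theta):
        pid = small_evaluator._patient_ids[0]
        fac = small_evaluator.interval_marginal_lik(pid, 2, six_theta, "mover")
        assert 0 < fac < 1


class TestKernelAgreement:
    def test_numba_and_numpy_paths_agree(self, small_evaluator, six_theta):
        from jointmsm import _kernels
        if not _kernels.HAVE_NUMBA:
            return
        U, V, logW, Uu, logWu = small_evaluator._pairs(six_theta)
        fast = small_evaluator._mover_group_ll(six_theta, U, V,
                                               small_evaluator._interval_of_row,
                                               small_evaluator.n_intervals)
        ref = small_evaluator._mover_group_ll_numpy(six_theta, U, V,
                                                    small_evaluator._interval_of_row,
                                                    small_evaluator.n_intervals)
        assert np.abs(fast - ref).max() < 1e-7

    def test_five_state_paths_agree(self, five_cohort):
        from jointmsm import _kernels
        cfg, th, cohort = five_cohort
        ev = jm.LikelihoodEvaluator(cohort.dataset, cfg)
        ll = ev.total_loglik(th)
        assert np.isfinite(ll)
        if _kernels.HAVE_NUMBA:
            U, V, logW, Uu, logWu = ev._pairs(th)
            fast = ev._mover_group_ll(th, U, V, ev._interval_of_row, ev.n_intervals)
            ref = ev._mover_group_ll_numpy(th, U, V, ev._interval_of_row, ev.n_intervals)
            assert np.abs(fast - ref).max() < 1e-7
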