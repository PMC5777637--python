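"""Shared fixtures: a reduced-design model configuration, a realistic true
parameter set, and small simulated cohorts (generated at test time)."""

import numpy as np
import pytest

import jointmsm as jm

REDUCED_DESIGN = {
    "AbarA": ("ama", "sex"),
    "AAbar": ("ama",),
    "DbarD": ("ama", "attained_damaged_count", "opposite_damaged"),
}

INTERCEPT_DESIGN = {"AbarA": (), "AAbar": (), "DbarD": ()}

FIVE_REDUCED_DESIGN = {
    "mu_Abar": ("ama",),
    "mu_A": ("ama",),
    "p_AbarD": ("opposite_damaged",),
    "p_AD": ("ama",),
}


def reduced_config(**kw) -> jm.ModelConfig:
    kw.setdefault("variant", "six_state")
    kw.setdefault("re_structure", "observation")
    kw.setdefault("quad_nodes", 7)
    kw.setdefault("design", REDUCED_DESIGN)
    return jm.ModelConfig(**kw)


def reduced_theta(config: jm.ModelConfig) -> jm.SixStateParams:
    """True values used throughout the simulation studies: activity and
    damage effects of realistic magnitude, stayer proportion 0.15,
    sigma_u^2 = 2, loading alpha = -0.4."""
    th = jm.SixStateParams.null(config)
    th.log_lam0 = {"AbarA": -1.6, "AAbar": 0.6, "DbarD": -6.5}
    th.beta = {"AbarA": np.array([2.0, -0.7]), "AAbar": np.array([-0.5]),
               "DbarD": np.array([2.0, 0.1, 0.8])}
    th.beta_damaged = {"AbarA": -0.15, "AAbar": -0.2}
    th.beta_active_DbarD = 1.6
    th.beta_stayer = {"AbarA": 1.2, "AAbar": 0.2}
    th.alpha = -0.4
    th.sigma2_u = 2.0
    th.sigma2_v = 2.0
    th.rho = 0.15
    th.pi = 0.15
    return th


def five_state_config(**kw) -> jm.ModelConfig:
    kw.setdefault("variant", "five_state")
    kw.setdefault("re_structure", "observation")
    kw.setdefault("quad_nodes", 7)
    kw.setdefault("design", FIVE_REDUCED_DESIGN)
    return jm.ModelConfig(**kw)


def five_state_theta(config: jm.ModelConfig) -> jm.FiveStateParams:
    th = jm.FiveStateParams.null(config)
    th.log_mu0 = {"Abar": 1.6, "A": -0.6}
    th.log_odds0 = {"AbarD": -4.0, "AD": -2.5}
    th.beta = {"mu_Abar": np.array([-2.0]), "mu_A": np.array([0.4]),
               "p_AbarD": np.array([1.0]), "p_AD": np.array([0.8])}
    th.beta_stayer = {"Abar": -1.5, "A": -0.2}
    th.alpha1 = -0.35
    th.alpha2 = 0.44
    th.sigma2_u = 2.0
    th.sigma2_v = 2.0
    th.rho = 0.0
    th.pi = 0.15
    return th


@pytest.fixture(scope="session")
def six_config():
    return reduced_config()


@pytest.fixture(scope="session")
def six_theta(six_config):
    return reduced_theta(six_config)


@pytest.fixture(scope="session")
def small_cohort(six_config, six_theta):
    """30 patients, 4-6 visits: large enough for every structural feature
    (movers/stayers, damage events) to appear."""
    sim = jm.SimConfig(n_patients=30, theta=six_theta, config=six_config,
                       seed=1234, visit_range=(4, 6))
    return jm.simulate_cohort(sim)


@pytest.fixture(scope="session")
def small_dataset(small_cohort):
    return small_cohort.dataset.validate()


@pytest.fixture(scope="session")
def small_evaluator(small_dataset, six_config):
    return jm.LikelihoodEvaluator(small_dataset, six_config)


@pytest.fixture(scope="session")
def five_cohort():
    cfg = five_state_config()
    th = five_state_theta(cfg)
    sim = jm.SimConfig(n_patients=25, theta=th, config=cfg, seed=555,
                       visit_range=(4, 6))
    return cfg, th, jm.simulate_cohort(sim)
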