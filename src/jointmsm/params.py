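"""Model configuration and parameter sets.

The six-state model is parameterised through three regression equations on
transition intensities (inactive->active, active->inactive,
undamaged->damaged), with the remaining intensities proportional to these via
scalar log-rate effects for damage status, current activity and latent
mover/stayer class, plus a bivariate normal random-effect pair (u, v) with a
loading ``alpha`` letting u act differently on the two activity intensities.

The five-state model regresses the mean sojourn times of the two undamaged
states (log link) and the jump probabilities to damage (logit link) directly,
with loadings ``alpha1``/``alpha2`` and stayer effects on the sojourn times.

Both share the variance components (sigma_u^2, sigma_v^2, rho) and the stayer
proportion ``pi``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .covariates import JOINT_TYPE_DUMMIES

__all__ = ["ModelConfig", "SixStateParams", "FiveStateParams", "default_design"]

_BASE_COVARIATES = ("ama", "attained_damaged_count", "opposite_damaged",
                    "sex", "age_onset", "duration")


def default_design(variant: str) -> dict[str, tuple[str, ...]]:
    """Per-transition covariate lists of the fitted models: joint-type dummies
    enter only the inactive->active and undamaged->damaged intensities of the
    six-state model and are absent from the five-state model."""
    with_jt = _BASE_COVARIATES[:3] + JOINT_TYPE_DUMMIES + _BASE_COVARIATES[3:]
    if variant == "six_state":
        return {"AbarA": with_jt, "AAbar": _BASE_COVARIATES, "DbarD": with_jt}
    if variant == "five_state":
        return {k: _BASE_COVARIATES for k in ("mu_Abar", "mu_A", "p_AbarD", "p_AD")}
    raise ValueError(f"unknown variant {variant!r}")


@dataclass
class ModelConfig:
    """What to fit: model variant, random-effect structure, quadrature size,
    per-transition covariate design and the AMA baseline-proxy switch."""

    variant: str = "six_state"
    re_structure: str = "observation"   # "observation" | "patient"
    quad_nodes: int | None = None       # default 15 (observation) / 30 (patient)
    design: Mapping[str, tuple[str, ...]] | None = None
    baseline_proxy_ama: bool = False

    def __post_init__(self) -> None:
        if self.variant not in ("six_state", "five_state"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.re_structure not in ("observation", "patient"):
            raise ValueError(f"unknown random-effect structure {self.re_structure!r}")
        if self.design is None:
            self.design = default_design(self.variant)
        else:
            self.design = {k: tuple(v) for k, v in self.design.items()}
            expected = set(default_design(self.variant))
            if set(self.design) != expected:
                raise ValueError(f"design must have keys {sorted(expected)}")
        if self.quad_nodes is None:
            self.quad_nodes = 15 if self.re_structure == "observation" else 30
        if self.quad_nodes < 1:
            raise ValueError("need at least one quadrature node per dimension")


def _check_common(p) -> None:
    if not (np.isfinite(p.sigma2_u) and p.sigma2_u > 0):
        raise ValueError(f"sigma2_u must be > 0, got {p.sigma2_u}")
    if not (np.isfinite(p.sigma2_v) and p.sigma2_v > 0):
        raise ValueError(f"sigma2_v must be > 0, got {p.sigma2_v}")
    if not (np.isfinite(p.rho) and abs(p.rho) < 1):
        raise ValueError(f"rho must lie in (-1, 1), got {p.rho}")
    # pi = 1 (all stayers) is a valid simulation setting; fitting rejects the
    # boundary when mapping to the working scale
    if not (np.isfinite(p.pi) and 0 <= p.pi <= 1):
        raise ValueError(f"pi must lie in [0, 1], got {p.pi}")


@dataclass
class SixStateParams:
    """Full parameter vector of the six-state intensity model."""

    log_lam0: dict[str, float]            # baselines: AbarA, AAbar, DbarD
    beta: dict[str, np.ndarray]           # per-transition regression vectors
    beta_damaged: dict[str, float]        # effect of damage on activity rates
    beta_active_DbarD: float              # effect of current activity on damage rate
    beta_stayer: dict[str, float]         # stayer effects on activity rates
    alpha: float
    sigma2_u: float
    sigma2_v: float
    rho: float
    pi: float

    variant = "six_state"

    def validate(self, config: ModelConfig) -> "SixStateParams":
        _check_common(self)
        for key in ("AbarA", "AAbar", "DbarD"):
            if key not in self.log_lam0:
                raise ValueError(f"missing baseline log_lam0[{key!r}]")
            b = np.asarray(self.beta[key], dtype=float)
            if b.shape != (len(config.design[key]),):
                raise ValueError(f"beta[{key!r}] has length {b.shape}, design expects "
                                 f"{len(config.design[key])}")
            self.beta[key] = b
        return self

    @classmethod
    def null(cls, config: ModelConfig) -> "SixStateParams":
        """All effects zero, unit rates, small variances — a valid interior point."""
        return cls(
            log_lam0={k: 0.0 for k in ("AbarA", "AAbar", "DbarD")},
            beta={k: np.zeros(len(config.design[k])) for k in ("AbarA", "AAbar", "DbarD")},
            beta_damaged={"AbarA": 0.0, "AAbar": 0.0},
            beta_active_DbarD=0.0,
            beta_stayer={"AbarA": 0.0, "AAbar": 0.0},
            alpha=1.0, sigma2_u=0.5, sigma2_v=0.5, rho=0.0, pi=0.1,
        )

    def flatten(self, config: ModelConfig) -> tuple[list[str], np.ndarray, list[str]]:
        """(names, natural-scale values, working transforms) in a fixed order."""
        names, vals, tr = [], [], []
        for k in ("AbarA", "AAbar", "DbarD"):
            names.append(f"log_lam0[{k}]"); vals.append(self.log_lam0[k]); tr.append("id")
        for k in ("AbarA", "AAbar", "DbarD"):
            for c, b in zip(config.design[k], self.beta[k]):
                names.append(f"beta[{k}][{c}]"); vals.append(b); tr.append("id")
        for k in ("AbarA", "AAbar"):
            names.append(f"beta_damaged[{k}]"); vals.append(self.beta_damaged[k]); tr.append("id")
        names.append("beta_active[DbarD]"); vals.append(self.beta_active_DbarD); tr.append("id")
        for k in ("AbarA", "AAbar"):
            names.append(f"beta_stayer[{k}]"); vals.append(self.beta_stayer[k]); tr.append("id")
        names.append("alpha"); vals.append(self.alpha); tr.append("id")
        names += ["sigma2_u", "sigma2_v", "rho", "pi"]
        vals += [self.sigma2_u, self.sigma2_v, self.rho, self.pi]
        tr += ["log", "log", "atanh", "logit"]
        return names, np.asarray(vals, dtype=float), tr

    def with_values(self, config: ModelConfig, values: np.ndarray) -> "SixStateParams":
        """Rebuild from a natural-scale vector in ``flatten`` order."""
        values = np.asarray(values, dtype=float)
        i = 0
        log_lam0 = {}
        for k in ("AbarA", "AAbar", "DbarD"):
            log_lam0[k] = float(values[i]); i += 1
        beta = {}
        for k in ("AbarA", "AAbar", "DbarD"):
            p = len(config.design[k])
            beta[k] = values[i: i + p].copy(); i += p
        beta_damaged = {"AbarA": float(values[i]), "AAbar": float(values[i + 1])}; i += 2
        beta_active = float(values[i]); i += 1
        beta_stayer = {"AbarA": float(values[i]), "AAbar": float(values[i + 1])}; i += 2
        alpha = float(values[i]); i += 1
        s2u, s2v, rho, pi = values[i: i + 4]
        return SixStateParams(log_lam0, beta, beta_damaged, beta_active, beta_stayer,
                              alpha, float(s2u), float(s2v), float(rho), float(pi))


@dataclass
class FiveStateParams:
    """Full parameter vector of the five-state sojourn/jump model."""

    log_mu0: dict[str, float]             # baseline mean sojourns: Abar, A
    log_odds0: dict[str, float]           # baseline jump-odds to damage: AbarD, AD
    beta: dict[str, np.ndarray]           # mu_Abar, mu_A, p_AbarD, p_AD
    beta_stayer: dict[str, float]         # stayer effects on mean sojourns: Abar, A
    alpha1: float
    alpha2: float
    sigma2_u: float
    sigma2_v: float
    rho: float
    pi: float

    variant = "five_state"

    def validate(self, config: ModelConfig) -> "FiveStateParams":
        _check_common(self)
        for key in ("mu_Abar", "mu_A", "p_AbarD", "p_AD"):
            b = np.asarray(self.beta[key], dtype=float)
            if b.shape != (len(config.design[key]),):
                raise ValueError(f"beta[{key!r}] has length {b.shape}, design expects "
                                 f"{len(config.design[key])}")
            self.beta[key] = b
        return self

    @classmethod
    def null(cls, config: ModelConfig) -> "FiveStateParams":
        return cls(
            log_mu0={"Abar": 0.0, "A": 0.0},
            log_odds0={"AbarD": -2.0, "AD": -2.0},
            beta={k: np.zeros(len(config.design[k]))
                  for k in ("mu_Abar", "mu_A", "p_AbarD", "p_AD")},
            beta_stayer={"Abar": 0.0, "A": 0.0},
            alpha1=1.0, alpha2=1.0, sigma2_u=0.5, sigma2_v=0.5, rho=0.0, pi=0.1,
        )

    def flatten(self, config: ModelConfig) -> tuple[list[str], np.ndarray, list[str]]:
        names, vals, tr = [], [], []
        for k in ("Abar", "A"):
            names.append(f"log_mu0[{k}]"); vals.append(self.log_mu0[k]); tr.append("id")
        for k in ("AbarD", "AD"):
            names.append(f"log_odds0[{k}]"); vals.append(self.log_odds0[k]); tr.append("id")
        for k in ("mu_Abar", "mu_A", "p_AbarD", "p_AD"):
            for c, b in zip(config.design[k], self.beta[k]):
                names.append(f"beta[{k}][{c}]"); vals.append(b); tr.append("id")
        for k in ("Abar", "A"):
            names.append(f"beta_stayer[{k}]"); vals.append(self.beta_stayer[k]); tr.append("id")
        names += ["alpha1", "alpha2", "sigma2_u", "sigma2_v", "rho", "pi"]
        vals += [self.alpha1, self.alpha2, self.sigma2_u, self.sigma2_v, self.rho, self.pi]
        tr += ["id", "id", "log", "log", "atanh", "logit"]
        return names, np.asarray(vals, dtype=float), tr

    def with_values(self, config: ModelConfig, values: np.ndarray) -> "FiveStateParams":
        values = np.asarray(values, dtype=float)
        i = 0
        log_mu0 = {"Abar": float(values[0]), "A": float(values[1])}
        log_odds0 = {"AbarD": float(values[2]), "AD": float(values[3])}
        i = 4
        beta = {}
        for k in ("mu_Abar", "mu_A", "p_AbarD", "p_AD"):
            p = len(config.design[k])
            beta[k] = values[i: i + p].copy(); i += p
        beta_stayer = {"Abar": float(values[i]), "A": float(values[i + 1])}; i += 2
        a1, a2, s2u, s2v, rho, pi = values[i: i + 6]
        return FiveStateParams(log_mu0, log_odds0, beta, beta_stayer,
                               float(a1), float(a2), float(s2u), float(s2v),
                               float(rho), float(pi))
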