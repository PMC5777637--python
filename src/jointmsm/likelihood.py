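"""Marginal likelihood for the clustered mover-stayer multistate models.

Per latent class, the conditional likelihood of one joint over one interval
is a transition-probability entry of the class's time-homogeneous chain with
covariates (and random effects) frozen at the visit opening the interval.
Within an interval, one bivariate normal draw (u, v) is shared by all 28
joints; the marginal interval factor integrates the 28-joint product over
(u, v) by nested Gauss-Hermite quadrature after factorising the bivariate
density as phi(v | u) phi(u).  Random effects are independent across
intervals, so the patient's conditional likelihood is the product of
per-interval marginal factors (observation-level structure); the patient-level
comparator instead wraps a single (u, v) integral around the whole product.

The mover-stayer mixture acts at the patient level: patients with observed
damage at the last visit (c* = 1) must be movers and contribute
(1 - pi) L_mover; damage-free patients contribute the mixture
(1 - pi) L_mover + pi L_stayer.

The first interval of every patient is excluded by default because the AMA
covariate is undefined at the first visit (the ``baseline_proxy_ama`` option
includes it using baseline activity as proxy).

All accumulation is in the log domain with log-sum-exp over quadrature nodes;
28-joint products underflow in the linear domain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .covariates import build_covariates
from .markov import (expm_mover3, expm_mover4, get_space, sojourn_jump_to_intensities,
                     transition_matrix)
from .params import FiveStateParams, ModelConfig, SixStateParams

__all__ = [
    "QuadratureRule",
    "conditional_intensities",
    "joint_interval_logprob",
    "LikelihoodEvaluator",
    "total_loglik",
]

_ETA_CLIP = 60.0  # linear predictors clipped to +/- this before exponentiation


@dataclass(frozen=True)
class QuadratureRule:
    """Gauss-Hermite rule restated for standard-normal expectations:
    E f(Z) ~ sum_k w_k f(x_k) with positive weights summing to one."""

    nodes: np.ndarray
    weights: np.ndarray

    @classmethod
    def gauss_hermite(cls, n: int) -> "QuadratureRule":
        if n < 1:
            raise ValueError("quadrature needs at least one node")
        x, w = np.polynomial.hermite.hermgauss(n)
        return cls(nodes=np.sqrt(2.0) * x, weights=w / np.sqrt(np.pi))


def conditional_intensities(theta, z, u: float, v: float, class_label: str,
                            config: ModelConfig) -> dict[tuple[int, int], float]:
    """Reference (scalar) map from parameters, covariates and random effects
    to the conditional transition intensities of one chain.

    ``z`` maps covariate names (the config design columns) to values.
    """
    def lp(key):
        val = sum(b * float(z[c]) for c, b in zip(config.design[key], theta.beta[key]))
        if not np.isfinite(val):
            bad = [c for c in config.design[key] if not np.isfinite(float(z[c]))]
            raise ValueError(f"non-finite linear predictor for {key}; offending covariates: {bad}")
        return val

    if config.variant == "six_state":
        l12 = np.exp(theta.log_lam0["AbarA"] + lp("AbarA") + u)
        l21 = np.exp(theta.log_lam0["AAbar"] + lp("AAbar") + theta.alpha * u)
        l13 = np.exp(theta.log_lam0["DbarD"] + lp("DbarD") + v)
        if class_label == "mover":
            return {
                (1, 2): l12, (2, 1): l21, (1, 3): l13,
                (2, 4): l13 * np.exp(theta.beta_active_DbarD),
                (3, 4): l12 * np.exp(theta.beta_damaged["AbarA"]),
                (4, 3): l21 * np.exp(theta.beta_damaged["AAbar"]),
            }
        return {
            (5, 6): l12 * np.exp(theta.beta_stayer["AbarA"]),
            (6, 5): l21 * np.exp(theta.beta_stayer["AAbar"]),
        }
    # five_state: regressions on mean sojourn times (log) and jump odds (logit)
    log_mu1 = theta.log_mu0["Abar"] + lp("mu_Abar") + u
    log_mu2 = theta.log_mu0["A"] + lp("mu_A") + theta.alpha1 * u
    odds13 = np.exp(theta.log_odds0["AbarD"] + lp("p_AbarD") + v)
    odds23 = np.exp(theta.log_odds0["AD"] + lp("p_AD") + theta.alpha2 * v)
    p13 = odds13 / (1.0 + odds13)
    p23 = odds23 / (1.0 + odds23)
    if class_label == "mover":
        from .markov import SojournJump
        sj = SojournJump(mu1=np.exp(log_mu1), mu2=np.exp(log_mu2),
                         mu4=1.0, mu5=1.0, p13=p13, p23=p23)
        lam = sojourn_jump_to_intensities(sj)
        return {k: lam[k] for k in ((1, 2), (2, 1), (1, 3), (2, 3))}
    mu4 = np.exp(log_mu1 + theta.beta_stayer["Abar"])
    mu5 = np.exp(log_mu2 + theta.beta_stayer["A"])
    return {(4, 5): 1.0 / mu4, (5, 4): 1.0 / mu5}


def joint_interval_logprob(state_from: int, state_to: int, dt: float,
                           Q: np.ndarray, space) -> float:
    """Log transition probability of one joint over one interval.

    States outside the class's space (e.g. a damaged state under the stayer
    chain) give -inf rather than raising: the mixture weights absorb the
    structural impossibility.
    """
    if state_from not in space.states or state_to not in space.states:
        return -np.inf
    P = transition_matrix(Q, dt)
    p = P[space.index(state_from), space.index(state_to)]
    with np.errstate(divide="ignore", invalid="ignore"):
        return float(np.log(p))


def _clip_exp(x):
    return np.exp(np.clip(x, -_ETA_CLIP, _ETA_CLIP))


class LikelihoodEvaluator:
    """Precomputes design matrices and interval structure for one dataset and
    model configuration, then evaluates the marginal log-likelihood for any
    parameter set.

    Joints that share identical covariate vectors and interval length within
    the dataset share one matrix exponential per quadrature node (exactness
    preserved; this is the dominant cost).
    """

    def __init__(self, dataset, config: ModelConfig, layout=None):
        self.dataset = dataset
        self.config = config
        layout = layout or dataset.layout
        cov = build_covariates(dataset, layout, config.baseline_proxy_ama)

        j = dataset.joints.sort_values(["patient_id", "joint_id", "visit_index"],
                                       kind="mergesort").reset_index(drop=True)
        cov = cov.sort_values(["patient_id", "joint_id", "visit_index"],
                              kind="mergesort").reset_index(drop=True)
        if not (j["patient_id"].to_numpy() == cov["patient_id"].to_numpy()).all():
            raise AssertionError("covariate table misaligned with joint table")

        # visit rank within patient (0-based ordinal of the visit)
        visit_rank = (j.groupby(["patient_id", "joint_id"], sort=False).cumcount()
                      .to_numpy())
        m_per = j.groupby("patient_id", sort=False)["visit_index"].transform("nunique").to_numpy()

        t = j["time_years"].to_numpy(dtype=float)
        a = j["active"].to_numpy(dtype=int)
        d = j["damaged"].to_numpy(dtype=int)

        # pair each row with the next visit of the same (patient, joint)
        grp_last = visit_rank == (m_per - 1)
        nxt_a = np.roll(a, -1)
        nxt_d = np.roll(d, -1)
        nxt_t = np.roll(t, -1)
        first_usable = 0 if config.baseline_proxy_ama else 1
        usable = (~grp_last) & (visit_rank >= first_usable)

        self._dt = (nxt_t - t)[usable]
        if np.any(self._dt <= 0):
            raise ValueError("zero-length or negative interval encountered; "
                             "validate the dataset (duplicate visit dates?)")
        a0, d0 = a[usable], d[usable]
        a1, d1 = nxt_a[usable], nxt_d[usable]
        if config.variant == "six_state":
            self._from = a0 + 2 * d0
            self._to = a1 + 2 * d1
        else:
            self._from = np.where(d0 == 1, 2, a0)
            self._to = np.where(d1 == 1, 2, a1)
        self._act_from = a0  # stayer-chain state (valid when no damage)

        pid = j["patient_id"].to_numpy()
        self._patient_ids = list(dataset.patients["patient_id"])
        pindex = {p: i for i, p in enumerate(self._patient_ids)}
        row_pat = np.array([pindex[p] for p in pid[usable]])
        self.n_patients = len(self._patient_ids)

        # global interval ids: one per (patient, visit_rank) among usable rows
        key = row_pat.astype(np.int64) * (m_per.max() + 1) + visit_rank[usable]
        uniq, self._interval_of_row = np.unique(key, return_inverse=True)
        self.n_intervals = len(uniq)
        self._interval_patient = np.zeros(self.n_intervals, dtype=int)
        self._interval_patient[self._interval_of_row] = row_pat
        self._interval_rank = np.zeros(self.n_intervals, dtype=int)
        self._interval_rank[self._interval_of_row] = visit_rank[usable]
        self._row_patient = row_pat

        cstar = dataset.c_star()
        self._c_star = cstar.to_numpy()
        self._stayer_rows = np.nonzero(self._c_star[row_pat] == 0)[0]
        if np.any(d0[self._stayer_rows] + d1[self._stayer_rows] > 0):
            raise ValueError("damage observed for a patient flagged c*=0; inconsistent data")

        # design matrices on unique (covariate vector, dt) rows
        cols = sorted(set().union(*config.design.values()))
        Z = cov[cols].to_numpy(dtype=float)[usable]
        if not np.all(np.isfinite(Z)):
            bad = [c for k, c in enumerate(cols) if not np.all(np.isfinite(Z[:, k]))]
            raise ValueError(f"non-finite covariate values in columns {bad}")
        key_mat = np.column_stack([Z, self._dt])
        _, uidx, self._uinv = np.unique(key_mat, axis=0, return_index=True,
                                        return_inverse=True)
        self._X = {k: Z[uidx][:, [cols.index(c) for c in config.design[k]]]
                   for k in config.design}
        self._udt = np.ascontiguousarray(self._dt[uidx])
        self.n_unique = len(uidx)
        self._uinv_i8 = np.ascontiguousarray(self._uinv, dtype=np.int64)
        self._from_i8 = np.ascontiguousarray(self._from, dtype=np.int64)
        self._to_i8 = np.ascontiguousarray(self._to, dtype=np.int64)

    # -- quadrature -------------------------------------------------------

    def _pairs(self, theta, rule: QuadratureRule | None = None):
        rule = rule or QuadratureRule.gauss_hermite(self.config.quad_nodes)
        x, w = rule.nodes, rule.weights
        su, sv, rho = np.sqrt(theta.sigma2_u), np.sqrt(theta.sigma2_v), theta.rho
        x1, x2 = np.meshgrid(x, x, indexing="ij")
        U = (su * x1).ravel()
        V = (rho * sv * x1 + sv * np.sqrt(1.0 - rho * rho) * x2).ravel()
        logW = (np.log(w)[:, None] + np.log(w)[None, :]).ravel()
        # the v integral of the stayer chain is free: marginalise analytically
        return U, V, logW, su * x, np.log(w)

    # -- conditional log-probability kernels ------------------------------

    def _mover_group_ll(self, theta, U, V, group, n_groups):
        """Sum of per-joint conditional log transition probabilities within
        each group (interval or patient), for each random-effect value.
        Returns (n_groups, len(U)).

        Dispatches to the compiled closed-form kernels when numba is
        available; the vectorised numpy path is the reference and the
        fallback (also taken when a kernel flags an ill-conditioned
        Sylvester system)."""
        from . import _kernels
        if _kernels.HAVE_NUMBA and len(U) > 1:
            out = np.empty((n_groups, len(U)))
            U = np.ascontiguousarray(U, dtype=float)
            V = np.ascontiguousarray(V, dtype=float)
            if self.config.variant == "six_state":
                e12 = theta.log_lam0["AbarA"] + self._X["AbarA"] @ theta.beta["AbarA"]
                e21 = theta.log_lam0["AAbar"] + self._X["AAbar"] @ theta.beta["AAbar"]
                e13 = theta.log_lam0["DbarD"] + self._X["DbarD"] @ theta.beta["DbarD"]
                bad = _kernels.mover6_group_ll(
                    e12, e21, e13, theta.alpha,
                    theta.beta_damaged["AbarA"], theta.beta_damaged["AAbar"],
                    theta.beta_active_DbarD, U, V, self._udt,
                    self._uinv_i8, self._from_i8, self._to_i8,
                    np.ascontiguousarray(group, dtype=np.int64), n_groups, out)
                if bad == 0:
                    return out
            else:
                c1 = theta.log_mu0["Abar"] + self._X["mu_Abar"] @ theta.beta["mu_Abar"]
                c2 = theta.log_mu0["A"] + self._X["mu_A"] @ theta.beta["mu_A"]
                c3 = theta.log_odds0["AbarD"] + self._X["p_AbarD"] @ theta.beta["p_AbarD"]
                c4 = theta.log_odds0["AD"] + self._X["p_AD"] @ theta.beta["p_AD"]
                _kernels.mover5_group_ll(
                    c1, c2, c3, c4, theta.alpha1, theta.alpha2, U, V, self._udt,
                    self._uinv_i8, self._from_i8, self._to_i8,
                    np.ascontiguousarray(group, dtype=np.int64), n_groups, out)
                return out
        return self._mover_group_ll_numpy(theta, U, V, group, n_groups)

    def _mover_group_ll_numpy(self, theta, U, V, group, n_groups):
        out = np.empty((n_groups, len(U)))
        inv, frm, to = self._uinv, self._from, self._to
        # quadrature nodes are processed in chunks so the batched matrix
        # exponential sees large inputs without exhausting memory
        chunk = max(1, 200_000 // max(self.n_unique, 1))
        if self.config.variant == "six_state":
            e12 = theta.log_lam0["AbarA"] + self._X["AbarA"] @ theta.beta["AbarA"]
            e21 = theta.log_lam0["AAbar"] + self._X["AAbar"] @ theta.beta["AAbar"]
            e13 = theta.log_lam0["DbarD"] + self._X["DbarD"] @ theta.beta["DbarD"]
            bd1, bd2 = theta.beta_damaged["AbarA"], theta.beta_damaged["AAbar"]
            ba = theta.beta_active_DbarD
            for lo in range(0, len(U), chunk):
                Uc, Vc = U[lo: lo + chunk, None], V[lo: lo + chunk, None]
                l12 = _clip_exp(e12[None, :] + Uc)
                l21 = _clip_exp(e21[None, :] + theta.alpha * Uc)
                l13 = _clip_exp(e13[None, :] + Vc)
                P = expm_mover4(l12, l21, l13, l13 * np.exp(ba),
                                l12 * np.exp(bd1), l21 * np.exp(bd2),
                                self._udt[None, :])
                with np.errstate(divide="ignore", invalid="ignore"):
                    logp = np.log(P[:, inv, frm, to])
                for k in range(logp.shape[0]):
                    out[:, lo + k] = np.bincount(group, weights=logp[k],
                                                 minlength=n_groups)
        else:
            c1 = theta.log_mu0["Abar"] + self._X["mu_Abar"] @ theta.beta["mu_Abar"]
            c2 = theta.log_mu0["A"] + self._X["mu_A"] @ theta.beta["mu_A"]
            c3 = theta.log_odds0["AbarD"] + self._X["p_AbarD"] @ theta.beta["p_AbarD"]
            c4 = theta.log_odds0["AD"] + self._X["p_AD"] @ theta.beta["p_AD"]
            for lo in range(0, len(U), chunk):
                Uc, Vc = U[lo: lo + chunk, None], V[lo: lo + chunk, None]
                inv_mu1 = _clip_exp(-(c1[None, :] + Uc))
                inv_mu2 = _clip_exp(-(c2[None, :] + theta.alpha1 * Uc))
                lo13 = np.clip(c3[None, :] + Vc, -_ETA_CLIP, _ETA_CLIP)
                lo23 = np.clip(c4[None, :] + theta.alpha2 * Vc, -_ETA_CLIP, _ETA_CLIP)
                p13 = 1.0 / (1.0 + np.exp(-lo13))
                p23 = 1.0 / (1.0 + np.exp(-lo23))
                P = expm_mover3((1.0 - p13) * inv_mu1, (1.0 - p23) * inv_mu2,
                                p13 * inv_mu1, p23 * inv_mu2, self._udt[None, :])
                with np.errstate(divide="ignore", invalid="ignore"):
                    logp = np.log(P[:, inv, frm, to])
                for k in range(logp.shape[0]):
                    out[:, lo + k] = np.bincount(group, weights=logp[k],
                                                 minlength=n_groups)
        return out

    def _stayer_group_ll(self, theta, Uu, group, n_groups):
        """Stayer 2-state chain log-likelihood sums per group per u node;
        v integrates out analytically.  Returns (n_groups, len(Uu))."""
        rows = self._stayer_rows
        if len(rows) == 0:
            return np.zeros((n_groups, len(Uu)))
        inv = self._uinv[rows]
        if self.config.variant == "six_state":
            e56 = (theta.log_lam0["AbarA"] + self._X["AbarA"] @ theta.beta["AbarA"]
                   + theta.beta_stayer["AbarA"])[inv]
            e65 = (theta.log_lam0["AAbar"] + self._X["AAbar"] @ theta.beta["AAbar"]
                   + theta.beta_stayer["AAbar"])[inv]
            lam_on = _clip_exp(e56[:, None] + Uu[None, :])
            lam_off = _clip_exp(e65[:, None] + theta.alpha * Uu[None, :])
        else:
            c1 = (theta.log_mu0["Abar"] + self._X["mu_Abar"] @ theta.beta["mu_Abar"]
                  + theta.beta_stayer["Abar"])[inv]
            c2 = (theta.log_mu0["A"] + self._X["mu_A"] @ theta.beta["mu_A"]
                  + theta.beta_stayer["A"])[inv]
            lam_on = _clip_exp(-(c1[:, None] + Uu[None, :]))
            lam_off = _clip_exp(-(c2[:, None] + theta.alpha1 * Uu[None, :]))
        dt = self._dt[rows][:, None]
        s = lam_on + lam_off
        decay = np.exp(-s * dt)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_on = np.where(s > 0, lam_on / np.where(s > 0, s, 1.0) * (1 - decay), 0.0)
            p_off = np.where(s > 0, lam_off / np.where(s > 0, s, 1.0) * (1 - decay), 0.0)
        frm = self._act_from[rows][:, None]
        to = np.where(self._to[rows] >= 1, 1, 0)[:, None]  # activity of end state
        P = np.where(frm == 0, np.where(to == 1, p_on, 1 - p_on),
                     np.where(to == 0, p_off, 1 - p_off))
        with np.errstate(divide="ignore", invalid="ignore"):
            logp = np.log(P)
        out = np.zeros((n_groups, len(Uu)))
        np.add.at(out, group[rows], logp)
        return out

    # -- marginal likelihoods ---------------------------------------------

    def class_logliks(self, theta, rule: QuadratureRule | None = None,
                      fixed_uv: tuple[float, float] | None = None):
        """Per-patient conditional-on-class log-likelihoods (L_mover, L_stayer).

        ``fixed_uv`` bypasses integration and evaluates the conditional
        likelihood at the given random-effect values (used for degenerate
        limits and diagnostics)."""
        if fixed_uv is not None:
            u0, v0 = fixed_uv
            U, V, logW = np.array([u0]), np.array([v0]), np.array([0.0])
            Uu, logWu = np.array([u0]), np.array([0.0])
        else:
            U, V, logW, Uu, logWu = self._pairs(theta, rule)

        if self.config.re_structure == "observation":
            m_ll = self._mover_group_ll(theta, U, V, self._interval_of_row, self.n_intervals)
            int_m = logsumexp(m_ll + logW[None, :], axis=1)
            Lm = np.bincount(self._interval_patient, weights=int_m,
                             minlength=self.n_patients)
            s_ll = self._stayer_group_ll(theta, Uu, self._interval_of_row, self.n_intervals)
            int_s = logsumexp(s_ll + logWu[None, :], axis=1)
            Ls = np.bincount(self._interval_patient, weights=int_s,
                             minlength=self.n_patients)
        else:
            m_ll = self._mover_group_ll(theta, U, V, self._row_patient, self.n_patients)
            Lm = logsumexp(m_ll + logW[None, :], axis=1)
            s_ll = self._stayer_group_ll(theta, Uu, self._row_patient, self.n_patients)
            Ls = logsumexp(s_ll + logWu[None, :], axis=1)
        # stayer likelihood is undefined (structurally zero) for c*=1 patients
        Ls = np.where(self._c_star == 1, -np.inf, Ls)
        return Lm, Ls

    def patient_logliks(self, theta, rule: QuadratureRule | None = None,
                        fixed_uv: tuple[float, float] | None = None) -> np.ndarray:
        """Marginal mover-stayer mixture log-likelihood per patient."""
        theta.validate(self.config) if hasattr(theta, "validate") else None
        Lm, Ls = self.class_logliks(theta, rule, fixed_uv)
        pi = theta.pi
        with np.errstate(divide="ignore", invalid="ignore"):
            log_pi = np.log(pi) if pi > 0 else -np.inf
            log_1mpi = np.log1p(-pi) if pi < 1 else -np.inf
            mover_term = log_1mpi + Lm
            # NaN from an overflowed exponential propagates to the caller's
            # finiteness check rather than warning here
            out = np.where(self._c_star == 1, mover_term,
                           np.logaddexp(mover_term, log_pi + Ls))
        return out

    def total_loglik(self, theta, rule: QuadratureRule | None = None,
                     fixed_uv: tuple[float, float] | None = None) -> float:
        ll = self.patient_logliks(theta, rule, fixed_uv)
        if not np.all(np.isfinite(ll)):
            bad = [self._patient_ids[i] for i in np.nonzero(~np.isfinite(ll))[0][:5]]
            raise FloatingPointError(
                f"non-finite log-likelihood contribution from patients {bad}")
        return float(ll.sum())

    def interval_marginal_lik(self, patient_id, j: int, theta, class_label: str,
                              rule: QuadratureRule | None = None) -> float:
        """Marginal likelihood factor of one usable interval (the one opened
        by the patient's ``j``-th visit, 1-based) under one latent class."""
        pidx = self._patient_ids.index(patient_id)
        first_usable = 1 if self.config.baseline_proxy_ama else 2
        sel = np.nonzero((self._interval_patient == pidx)
                         & (self._interval_rank == j - 1))[0]
        if len(sel) == 0:
            raise ValueError(
                f"patient {patient_id} has no usable interval opened by visit {j} "
                f"(usable visits start at {first_usable})")
        gid = sel[0]
        U, V, logW, Uu, logWu = self._pairs(theta, rule)
        if class_label == "mover":
            ll = self._mover_group_ll(theta, U, V, self._interval_of_row, self.n_intervals)
            return float(np.exp(logsumexp(ll[gid] + logW)))
        ll = self._stayer_group_ll(theta, Uu, self._interval_of_row, self.n_intervals)
        return float(np.exp(logsumexp(ll[gid] + logWu)))

    def n_parameters(self, theta) -> int:
        return len(theta.flatten(self.config)[1])


def total_loglik(dataset, theta, config: ModelConfig, **kw) -> float:
    """Marginal log-likelihood of a dataset (convenience wrapper)."""
    return LikelihoodEvaluator(dataset, config).total_loglik(theta, **kw)
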