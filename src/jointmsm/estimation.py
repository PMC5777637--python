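"""Maximum-likelihood fitting, standard errors, and profile likelihood.

Fitting maximises the marginal log-likelihood with BFGS on a working
(unconstrained) scale: log for variance components, atanh for the
random-effect correlation, logit for the stayer proportion, identity for
regression coefficients, loadings and log-baselines.  Standard errors come
from the numerically derived (central-difference) Hessian at the optimum;
Wald intervals are formed on the working scale and back-transformed, which
yields the usual asymmetric intervals for variances and the stayer
proportion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .likelihood import LikelihoodEvaluator
from .params import ModelConfig

__all__ = ["FitResult", "ProfileCurve", "to_working_scale", "from_working_scale",
           "fit", "standard_errors", "profile_pi",
           "compare_random_effect_structures", "crude_start"]


def _fwd(value: float, transform: str) -> float:
    if transform == "id":
        return value
    if transform == "log":
        if value <= 0:
            raise ValueError("parameter at or below its boundary (<= 0); "
                             "refit with this parameter fixed instead")
        return np.log(value)
    if transform == "atanh":
        if not -1 < value < 1:
            raise ValueError("correlation outside (-1, 1)")
        return np.arctanh(value)
    if transform == "logit":
        if not 0 < value < 1:
            raise ValueError("probability at a boundary (0 or 1); "
                             "refit with this parameter fixed instead")
        return np.log(value / (1 - value))
    raise ValueError(f"unknown transform {transform!r}")


def _inv(value: float, transform: str) -> float:
    if transform == "id":
        return value
    if transform == "log":
        return np.exp(value)
    if transform == "atanh":
        return np.tanh(value)
    if transform == "logit":
        return 1.0 / (1.0 + np.exp(-value))
    raise ValueError(f"unknown transform {transform!r}")


def to_working_scale(theta, config: ModelConfig):
    """(names, working vector, transforms) for a parameter set."""
    names, vals, tr = theta.flatten(config)
    work = np.array([_fwd(v, t) for v, t in zip(vals, tr)])
    return names, work, tr


def from_working_scale(theta_template, config: ModelConfig, work: np.ndarray):
    """Rebuild a parameter set from a working-scale vector."""
    _, _, tr = theta_template.flatten(config)
    nat = np.array([_inv(v, t) for v, t in zip(work, tr)])
    return theta_template.with_values(config, nat)


@dataclass
class FitResult:
    """Maximum-likelihood fit: estimates, uncertainty, diagnostics."""

    theta: object
    config: ModelConfig
    loglik: float
    names: list[str]
    transforms: list[str]
    working: np.ndarray          # full working-scale vector at the optimum
    free: np.ndarray             # boolean mask of optimised entries
    converged: bool
    message: str
    n_iter: int
    n_evals: int
    trace: list[float] = field(default_factory=list)   # best-so-far log-likelihoods
    hessian: np.ndarray | None = None      # of the log-likelihood, free block
    se_working: np.ndarray | None = None   # NaN at fixed entries
    ci_lower: np.ndarray | None = None     # natural scale
    ci_upper: np.ndarray | None = None

    def summary(self) -> pd.DataFrame:
        nat = [_inv(v, t) for v, t in zip(self.working, self.transforms)]
        out = pd.DataFrame({"parameter": self.names, "estimate": nat,
                            "working": self.working, "transform": self.transforms,
                            "free": self.free})
        if self.se_working is not None:
            out["se_working"] = self.se_working
            out["ci_lower"] = self.ci_lower
            out["ci_upper"] = self.ci_upper
        return out

    def to_json(self, path, seed=None, extra: dict | None = None) -> None:
        from . import __version__
        payload = {
            "loglik": self.loglik,
            "converged": self.converged,
            "message": self.message,
            "n_iter": self.n_iter,
            "n_evals": self.n_evals,
            "variant": self.config.variant,
            "re_structure": self.config.re_structure,
            "quad_nodes": self.config.quad_nodes,
            "seed": seed,
            "version": __version__,
            "parameters": self.summary().to_dict(orient="records"),
        }
        if extra:
            payload.update(extra)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, default=float)


@dataclass
class ProfileCurve:
    """Profile log-likelihood of the stayer proportion."""

    grid: np.ndarray
    loglik: np.ndarray
    converged: np.ndarray

    @property
    def argmax(self) -> float:
        return float(self.grid[int(np.argmax(self.loglik))])


def crude_start(dataset, config: ModelConfig):
    """Starting values from crude observed transition counts over person-time,
    ignoring clustering: coefficients at 0, variances at 0.5, correlation at
    0, stayer proportion at 0.2 x the damage-free fraction."""
    from .params import FiveStateParams, SixStateParams

    j = dataset.joints.sort_values(["patient_id", "joint_id", "visit_index"],
                                   kind="mergesort")
    code = (j["active"] + 2 * j["damaged"]).to_numpy()
    t = j["time_years"].to_numpy(dtype=float)
    pidjid = j[["patient_id", "joint_id"]].to_numpy()
    same = (pidjid[1:] == pidjid[:-1]).all(axis=1)
    frm, to, dt = code[:-1][same], code[1:][same], np.diff(t)[same]

    def rate(n_events, time_at_risk, lo=-8.0, hi=3.0):
        if time_at_risk <= 0 or n_events == 0:
            return lo
        return float(np.clip(np.log(n_events / time_at_risk), lo, hi))

    T = {s: dt[frm == s].sum() for s in range(4)}
    n = {(r, s): int(((frm == r) & (to == s)).sum()) for r in range(4) for s in range(4)}
    damage_free = float(1.0 - dataset.c_star().mean())
    pi0 = float(np.clip(0.2 * damage_free, 0.01, 0.5))

    if config.variant == "six_state":
        theta = SixStateParams.null(config)
        theta.log_lam0["AbarA"] = rate(n[(0, 1)] + n[(2, 3)], T[0] + T[2])
        theta.log_lam0["AAbar"] = rate(n[(1, 0)] + n[(3, 2)], T[1] + T[3])
        theta.log_lam0["DbarD"] = rate(n[(0, 2)] + n[(1, 3)], T[0] + T[1])
        theta.alpha = 1.0
        theta.pi = pi0
        return theta
    theta = FiveStateParams.null(config)
    exits0 = n[(0, 1)] + n[(0, 2)] + n[(0, 3)]
    exits1 = n[(1, 0)] + n[(1, 2)] + n[(1, 3)]
    theta.log_mu0["Abar"] = -rate(exits0, T[0])
    theta.log_mu0["A"] = -rate(exits1, T[1])
    p13 = np.clip((n[(0, 2)] + n[(0, 3)]) / max(exits0, 1), 0.005, 0.5)
    p23 = np.clip((n[(1, 2)] + n[(1, 3)]) / max(exits1, 1), 0.005, 0.5)
    theta.log_odds0["AbarD"] = float(np.log(p13 / (1 - p13)))
    theta.log_odds0["AD"] = float(np.log(p23 / (1 - p23)))
    theta.pi = pi0
    return theta


def fit(dataset, config: ModelConfig, start=None, *,
        fixed: dict[str, float] | None = None,
        evaluator: LikelihoodEvaluator | None = None,
        gtol: float = 1e-4, maxiter: int = 500, grad_tol: float = 5e-3,
        restarts: int = 1, rescue_mixture: bool = True,
        callback: Callable | None = None) -> FitResult:
    """Maximise the marginal log-likelihood with BFGS on the working scale.

    ``fixed`` maps parameter names (as in ``theta.flatten``) to natural-scale
    values held constant during optimisation (used by the profile likelihood).
    Deterministic given the start and options.

    Convergence is assessed with an accurate central-difference gradient at
    the returned point: the line search's own stopping signal is unreliable
    near the optimum because forward-difference gradients hit the roundoff
    floor of a log-likelihood of magnitude 10^3-10^4.  If the assessment
    fails, BFGS is restarted (fresh curvature estimate) up to ``restarts``
    times.

    The mover-stayer mixture has a spurious local optimum in which the
    stayer-effect coefficients run onto their plateau (a stayer chain so fast
    it is uninformative) and pi collapses to 0, after which the stayer block
    is flat.  When ``rescue_mixture`` is set (default) and a free pi ends
    below 0.01 from a start of at least 0.02, the fit is repeated once from
    the collapsed solution with the stayer effects reset to zero and pi
    re-opened; the solution with the higher log-likelihood is returned.
    """
    ev = evaluator or LikelihoodEvaluator(dataset, config)
    theta0 = start if start is not None else crude_start(dataset, config)
    theta0.validate(config)
    names, work0, transforms = to_working_scale(theta0, config)
    free = np.ones(len(work0), dtype=bool)
    if fixed:
        for nm, val in fixed.items():
            if nm not in names:
                raise ValueError(f"unknown parameter {nm!r}")
            k = names.index(nm)
            work0[k] = _fwd(val, transforms[k])
            free[k] = False

    full = work0.copy()
    trace: list[float] = []
    n_evals = 0

    def negll(x_free: np.ndarray) -> float:
        nonlocal n_evals
        n_evals += 1
        w = full.copy()
        w[free] = x_free
        try:
            th = from_working_scale(theta0, config, w)
            ll = ev.total_loglik(th)
        except FloatingPointError:
            return 1e12
        if not np.isfinite(ll):
            return 1e12
        if not trace or ll > trace[-1]:
            trace.append(ll)
        else:
            trace.append(trace[-1])
        return -ll

    f0 = negll(work0[free])
    if not np.isfinite(f0) or f0 >= 1e12:
        raise ValueError("log-likelihood is not finite at the starting values")

    def central_grad(x, h=1e-4):
        g = np.empty(len(x))
        for i in range(len(x)):
            e = np.zeros(len(x)); e[i] = h
            g[i] = (negll(x + e) - negll(x - e)) / (2 * h)
        return g

    x = work0[free]
    n_iter = 0
    message = ""
    converged = False
    for attempt in range(restarts + 1):
        res = minimize(negll, x, method="BFGS",
                       options={"gtol": gtol, "maxiter": maxiter}, callback=callback)
        x = res.x
        n_iter += int(res.nit)
        message = str(res.message)
        gmax = float(np.abs(central_grad(x)).max()) if len(x) else 0.0
        converged = gmax < grad_tol
        if converged or res.success:
            converged = converged or bool(res.success)
            break
    full[free] = x
    theta_hat = from_working_scale(theta0, config, full)
    loglik = ev.total_loglik(theta_hat)   # re-evaluation check: reported = actual
    result = FitResult(theta=theta_hat, config=config, loglik=float(loglik),
                       names=names, transforms=transforms, working=full, free=free,
                       converged=converged, message=message,
                       n_iter=n_iter, n_evals=n_evals, trace=trace)

    pi_free = "pi" in names and free[names.index("pi")]
    if (rescue_mixture and pi_free and hasattr(theta_hat, "beta_stayer")
            and theta_hat.pi < 0.01 and theta0.pi >= 0.02):
        import copy as _copy
        alt_start = _copy.deepcopy(theta_hat)
        alt_start.beta_stayer = {k: 0.0 for k in alt_start.beta_stayer}
        alt_start.pi = max(theta0.pi, 0.05)
        alt = fit(dataset, config, start=alt_start, fixed=fixed, evaluator=ev,
                  gtol=gtol, maxiter=maxiter, grad_tol=grad_tol,
                  restarts=restarts, rescue_mixture=False, callback=callback)
        if alt.loglik > result.loglik:
            return alt
    return result


def _central_hessian(f, x, step=1e-4):
    """Central-difference Hessian of scalar f at x (2n^2 evaluations)."""
    n = len(x)
    H = np.empty((n, n))
    for i in range(n):
        ei = np.zeros(n); ei[i] = step
        H[i, i] = (f(x + ei) - 2.0 * f(x) + f(x - ei)) / step**2
        for k in range(i + 1, n):
            ek = np.zeros(n); ek[k] = step
            H[i, k] = H[k, i] = (f(x + ei + ek) - f(x + ei - ek)
                                 - f(x - ei + ek) + f(x - ei - ek)) / (4.0 * step**2)
    return H


def _forward_hessian(f, x, step=1e-4):
    """Mixed-scheme Hessian: central second differences on the diagonal,
    forward differences for the cross terms reusing the f(x + h e_i) stencil
    (n(n-1)/2 + 2n + 1 evaluations; first-order cross-term accuracy)."""
    n = len(x)
    H = np.empty((n, n))
    f0 = f(x)
    fp = np.empty(n)
    for i in range(n):
        ei = np.zeros(n); ei[i] = step
        fp[i] = f(x + ei)
        H[i, i] = (fp[i] - 2.0 * f0 + f(x - ei)) / step**2
    for i in range(n):
        ei = np.zeros(n); ei[i] = step
        for k in range(i + 1, n):
            ek = np.zeros(n); ek[k] = step
            H[i, k] = H[k, i] = (f(x + ei + ek) - fp[i] - fp[k] + f0) / step**2
    return H


def standard_errors(fit_result: FitResult, evaluator: LikelihoodEvaluator,
                    step: float = 5e-3, scheme: str = "central",
                    z: float = 1.959963984540054) -> FitResult:
    """Standard errors and 95% Wald intervals from the numerically derived
    Hessian of the log-likelihood at the optimum (central differences on the
    working scale, then inverted).

    The default step balances truncation error against the roundoff floor of
    a log-likelihood of magnitude 10^3-10^4 (second differences amplify
    roundoff by 1/step^2; 1e-4 would be noise-dominated).  ``scheme`` selects
    the stencil: "central" (default, 2n^2 evaluations) or "forward"
    (~n^2/2 evaluations, first-order cross terms — a documented cost/accuracy
    trade for expensive likelihoods)."""
    names = fit_result.names
    free = fit_result.free
    full = fit_result.working.copy()
    config = fit_result.config
    template = fit_result.theta

    def ll(x_free):
        w = full.copy()
        w[free] = x_free
        return evaluator.total_loglik(from_working_scale(template, config, w))

    if scheme not in ("central", "forward"):
        raise ValueError(f"unknown Hessian scheme {scheme!r}")
    hess = _central_hessian if scheme == "central" else _forward_hessian
    H = hess(ll, full[free], step=step)
    eigvals, eigvecs = np.linalg.eigh(H)
    if np.any(eigvals >= 0):
        k = int(np.argmax(eigvals))
        flat = int(np.argmax(np.abs(eigvecs[:, k])))
        free_names = [n for n, fr in zip(names, free) if fr]
        raise np.linalg.LinAlgError(
            f"Hessian is not negative definite at the reported optimum; flattest "
            f"direction loads on parameter {free_names[flat]!r} "
            f"(eigenvalue {eigvals[k]:.3g})")
    cov = np.linalg.inv(-H)
    se_free = np.sqrt(np.diag(cov))
    se = np.full(len(names), np.nan)
    se[free] = se_free
    lo_w = full - z * np.where(np.isnan(se), 0.0, se)
    hi_w = full + z * np.where(np.isnan(se), 0.0, se)
    tr = fit_result.transforms
    fit_result.hessian = H
    fit_result.se_working = se
    fit_result.ci_lower = np.array([_inv(v, t) for v, t in zip(lo_w, tr)])
    fit_result.ci_upper = np.array([_inv(v, t) for v, t in zip(hi_w, tr)])
    fit_result.ci_lower[~free] = np.nan
    fit_result.ci_upper[~free] = np.nan
    return fit_result


def profile_pi(dataset, config: ModelConfig, grid, start=None, *,
               evaluator: LikelihoodEvaluator | None = None,
               maxiter: int = 200, **fit_kw) -> ProfileCurve:
    """Profile log-likelihood for the stayer proportion: at each grid value of
    pi, maximise over every other parameter (warm-starting from the previous
    grid point)."""
    grid = np.asarray(grid, dtype=float)
    if np.any((grid <= 0) | (grid >= 1)):
        raise ValueError("profile grid must lie strictly inside (0, 1)")
    ev = evaluator or LikelihoodEvaluator(dataset, config)
    values = np.empty(len(grid))
    ok = np.zeros(len(grid), dtype=bool)
    current = start if start is not None else crude_start(dataset, config)
    for k, p in enumerate(grid):
        current.pi = float(p)
        res = fit(dataset, config, start=current, fixed={"pi": float(p)},
                  evaluator=ev, maxiter=maxiter, **fit_kw)
        values[k] = res.loglik
        ok[k] = res.converged
        current = res.theta
    return ProfileCurve(grid=grid, loglik=values, converged=ok)


def compare_random_effect_structures(dataset, config: ModelConfig, *,
                                     quad_nodes: tuple[int, int] | None = None,
                                     start=None, maxiter: int = 500,
                                     **fit_kw) -> dict:
    """Fit the observation-level and patient-level random-effects structures
    and report their maximised log-likelihoods (the models are non-nested but
    have equal parameter counts, so raw log-likelihoods compare directly)."""
    results = {}
    for idx, structure in enumerate(("observation", "patient")):
        cfg = ModelConfig(variant=config.variant, re_structure=structure,
                          quad_nodes=(quad_nodes[idx] if quad_nodes else None),
                          design=config.design,
                          baseline_proxy_ama=config.baseline_proxy_ama)
        res = fit(dataset, cfg, start=start, maxiter=maxiter, **fit_kw)
        results[structure] = res
    n_obs = len(results["observation"].names)
    n_pat = len(results["patient"].names)
    assert n_obs == n_pat, "structures must have equal parameter counts"
    return {
        "loglik_observation": results["observation"].loglik,
        "loglik_patient": results["patient"].loglik,
        "difference": results["observation"].loglik - results["patient"].loglik,
        "n_parameters": n_obs,
        "fits": results,
    }
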