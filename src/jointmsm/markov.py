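"""Continuous-time Markov machinery for the joint activity/damage state spaces.

Two model variants are supported, each split into two conditional chains that
never communicate (latent mover/stayer class):

* six_state — movers follow a reversible 4-state chain over
  (activity x damage) with irreversible damage
  (states 1=inactive/undamaged, 2=active/undamaged, 3=inactive/damaged,
  4=active/damaged); stayers follow a 2-state activity chain (states 5, 6).
* five_state — movers follow a 3-state chain with a single absorbing damaged
  state (1=inactive/undamaged, 2=active/undamaged, 3=damaged); stayers follow
  a 2-state activity chain (states 4, 5).

Transition probabilities over an interval are P(t) = expm(Q t).  The public
:func:`transition_matrix` uses scipy's scaling-and-squaring Pade expm; the
vectorised kernels (`expm_two_state`, `expm_mover4`, `expm_mover3`) exploit the
block-triangular structure of these particular chains and are the likelihood
hot path.  They are cross-validated against expm and an ODE oracle in the test
suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.linalg import expm as _scipy_expm

__all__ = [
    "StateSpace",
    "SojournJump",
    "get_space",
    "build_generator",
    "transition_matrix",
    "sojourn_jump_to_intensities",
    "intensities_to_sojourn_jump",
    "expm_two_state",
    "expm_mover4",
    "expm_mover3",
]


@dataclass(frozen=True)
class StateSpace:
    """One conditional chain: a model variant restricted to a latent class."""

    variant: str          # "six_state" | "five_state"
    class_label: str      # "mover" | "stayer"
    states: tuple[int, ...]            # global state labels
    transitions: tuple[tuple[int, int], ...]  # allowed (from, to), global labels

    @property
    def n_states(self) -> int:
        return len(self.states)

    def index(self, state: int) -> int:
        """Local (0-based) index of a global state label."""
        try:
            return self.states.index(state)
        except ValueError:
            raise ValueError(f"state {state} not in {self.variant}/{self.class_label} space") from None


SIX_MOVER = StateSpace(
    "six_state", "mover", (1, 2, 3, 4),
    ((1, 2), (2, 1), (1, 3), (2, 4), (3, 4), (4, 3)),
)
SIX_STAYER = StateSpace("six_state", "stayer", (5, 6), ((5, 6), (6, 5)))
FIVE_MOVER = StateSpace(
    "five_state", "mover", (1, 2, 3),
    ((1, 2), (2, 1), (1, 3), (2, 3)),
)
FIVE_STAYER = StateSpace("five_state", "stayer", (4, 5), ((4, 5), (5, 4)))

_SPACES = {
    ("six_state", "mover"): SIX_MOVER,
    ("six_state", "stayer"): SIX_STAYER,
    ("five_state", "mover"): FIVE_MOVER,
    ("five_state", "stayer"): FIVE_STAYER,
}


def get_space(variant: str, class_label: str) -> StateSpace:
    try:
        return _SPACES[(variant, class_label)]
    except KeyError:
        raise ValueError(f"unknown state space {variant!r}/{class_label!r}") from None


def build_generator(intensities: Mapping[tuple[int, int], float],
                    space: StateSpace) -> np.ndarray:
    """Assemble the generator matrix Q for one conditional chain.

    ``intensities`` maps allowed (from, to) global state pairs to nonnegative
    rates (events per year); omitted transitions get rate 0.  Off-diagonal
    entries are the rates, the diagonal is the negative row sum.
    """
    n = space.n_states
    Q = np.zeros((n, n))
    allowed = set(space.transitions)
    for key, rate in intensities.items():
        key = tuple(key)
        if key not in allowed:
            raise ValueError(
                f"transition {key[0]}->{key[1]} is not allowed in the "
                f"{space.variant}/{space.class_label} space")
        if not np.isfinite(rate) or rate < 0:
            raise ValueError(f"intensity for {key[0]}->{key[1]} must be finite and >= 0, got {rate}")
        Q[space.index(key[0]), space.index(key[1])] = rate
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def transition_matrix(Q: np.ndarray, dt: float) -> np.ndarray:
    """Transition-probability matrix P(dt) = expm(Q * dt).

    Tiny negative entries (>= -1e-12, floating-point noise from the Pade
    evaluation) are clamped to 0 and rows renormalised; anything more negative
    raises.
    """
    Q = np.asarray(Q, dtype=float)
    if not np.all(np.isfinite(Q)):
        raise ValueError("generator matrix contains non-finite entries")
    if not np.isfinite(dt) or dt < 0:
        raise ValueError(f"interval length must be >= 0, got {dt}")
    if dt == 0:
        return np.eye(Q.shape[0])
    P = _scipy_expm(Q * dt)
    if not np.all(np.isfinite(P)):
        raise FloatingPointError("matrix exponential overflowed (rates too large)")
    if P.min() < -1e-12:
        raise FloatingPointError(f"transition matrix entry {P.min()} below tolerance")
    P = np.clip(P, 0.0, None)
    P /= P.sum(axis=1, keepdims=True)
    return P


@dataclass(frozen=True)
class SojournJump:
    """Sojourn/jump parameterisation of the five-state model.

    mu1/mu2: mean sojourn times (years) in the undamaged inactive/active
    states for movers; mu4/mu5 the same for stayers; p13/p23 the probabilities
    that the jump out of state 1 (resp. 2) goes directly to damage.
    """

    mu1: float
    mu2: float
    mu4: float
    mu5: float
    p13: float
    p23: float

    def validate(self) -> None:
        for name in ("mu1", "mu2", "mu4", "mu5"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"mean sojourn time {name} must be finite and > 0, got {v}")
        for name in ("p13", "p23"):
            v = getattr(self, name)
            if not np.isfinite(v) or not 0 < v < 1:
                raise ValueError(f"jump probability {name} must lie strictly in (0,1), got {v}")


def sojourn_jump_to_intensities(sj: SojournJump) -> dict[tuple[int, int], float]:
    """Map mean sojourn times and jump probabilities to transition intensities.

    lambda_12 = (1-p13)/mu1, lambda_13 = p13/mu1, lambda_21 = (1-p23)/mu2,
    lambda_23 = p23/mu2, lambda_45 = 1/mu4, lambda_54 = 1/mu5.
    """
    sj.validate()
    return {
        (1, 2): (1.0 - sj.p13) / sj.mu1,
        (1, 3): sj.p13 / sj.mu1,
        (2, 1): (1.0 - sj.p23) / sj.mu2,
        (2, 3): sj.p23 / sj.mu2,
        (4, 5): 1.0 / sj.mu4,
        (5, 4): 1.0 / sj.mu5,
    }


def intensities_to_sojourn_jump(intensities: Mapping[tuple[int, int], float]) -> SojournJump:
    """Inverse map: mu_r = 1/sum_k lambda_rk, p_rk = lambda_rk / sum_k lambda_rk."""
    lam = {tuple(k): float(v) for k, v in intensities.items()}
    exits = {1: (1, 2, 1, 3), 2: (2, 1, 2, 3), 4: (4, 5, None, None), 5: (5, 4, None, None)}
    mu: dict[int, float] = {}
    p: dict[int, float] = {}
    for state, (a0, a1, b0, b1) in exits.items():
        total = lam.get((a0, a1), 0.0) + (lam.get((b0, b1), 0.0) if b0 is not None else 0.0)
        if total <= 0:
            raise ValueError(f"total exit rate from state {state} is zero; "
                             "mean sojourn time is undefined")
        mu[state] = 1.0 / total
        if b0 is not None:
            p[state] = lam.get((b0, b1), 0.0) / total
    return SojournJump(mu1=mu[1], mu2=mu[2], mu4=mu[4], mu5=mu[5],
                       p13=p[1], p23=p[2])


# ---------------------------------------------------------------------------
# vectorised closed-form kernels
# ---------------------------------------------------------------------------

def expm_two_state(a, b, dt):
    """exp(Q t) for stochastic 2-state generators, vectorised.

    ``a`` is the 1->2 rate, ``b`` the 2->1 rate.  Shapes broadcast; returns
    (..., 2, 2).  P11 = (b + a e^{-st})/s with s = a + b (identity when s=0).
    """
    a, b, dt = np.broadcast_arrays(*(np.asarray(x, dtype=float) for x in (a, b, dt)))
    s = a + b
    with np.errstate(divide="ignore", invalid="ignore"):
        decay = np.exp(-s * dt)
        p12 = np.where(s > 0, a / np.where(s > 0, s, 1.0) * (1.0 - decay), 0.0)
        p21 = np.where(s > 0, b / np.where(s > 0, s, 1.0) * (1.0 - decay), 0.0)
    P = np.empty(a.shape + (2, 2))
    P[..., 0, 0] = 1.0 - p12
    P[..., 0, 1] = p12
    P[..., 1, 0] = p21
    P[..., 1, 1] = 1.0 - p21
    return P


def _expm2_general(A, dt):
    """exp(A t) for batches of general real 2x2 matrices with real spectrum.

    Uses e^{At} = e^{tau t} [cosh(d t) I + sinh(d t)/d (A - tau I)], where
    tau is the mean of the eigenvalues and d the half-gap; valid when
    (a11-a22)^2/4 + a12 a21 >= 0, which holds for the Metzler-like blocks of
    these chains (off-diagonals nonnegative).
    """
    A = np.asarray(A, dtype=float)
    dt = np.asarray(dt, dtype=float)
    a11, a12 = A[..., 0, 0], A[..., 0, 1]
    a21, a22 = A[..., 1, 0], A[..., 1, 1]
    tau = 0.5 * (a11 + a22)
    disc = 0.25 * (a11 - a22) ** 2 + a12 * a21
    d = np.sqrt(np.maximum(disc, 0.0))
    # eigenvalues tau +/- d are both <= 0 for these (sub)generator blocks,
    # so exponentiate them directly: no cosh/sinh overflow for large rates.
    # tau + d can turn slightly positive through cancellation at huge rates;
    # clamp to the mathematically guaranteed sign.
    ep = np.exp(np.minimum(tau + d, 0.0) * dt)
    em = np.exp((tau - d) * dt)
    cosh_term = 0.5 * (ep + em)
    x = d * dt
    small = x < 1e-6
    # sinh(d t)/d = t * sinhc(d t); use the series when d t is tiny
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(small,
                     dt * np.exp(tau * dt) * (1.0 + x * x / 6.0),
                     (ep - em) / np.where(small, 1.0, 2.0 * d))
    out = np.empty(np.broadcast(a11, dt).shape + (2, 2))
    out[..., 0, 0] = cosh_term + f * (a11 - tau)
    out[..., 0, 1] = f * a12
    out[..., 1, 0] = f * a21
    out[..., 1, 1] = cosh_term + f * (a22 - tau)
    return out


def expm_mover4(lam12, lam21, lam13, lam24, lam34, lam43, dt):
    """Transition probabilities for the 4-state mover chain, vectorised.

    The generator is block upper triangular,

        Q = [[A, B], [0, C]],

    with A the undamaged activity block (exit rates to damage on its
    diagonal), B = diag(lam13, lam24) and C the damaged activity block.  Then
    P(t) = [[e^{At}, X(t)], [0, e^{Ct}]] where X solves the Sylvester equation
    A X - X C = e^{At} B - B e^{Ct} (integrate d/dt of the variation-of-
    constants form).  The 2x2 exponentials are closed form and the Sylvester
    system is a batched 4x4 linear solve; rows where A and C share an
    eigenvalue (singular system) fall back to scipy expm.
    """
    lam12, lam21, lam13, lam24, lam34, lam43, dt = np.broadcast_arrays(
        *(np.asarray(x, dtype=float) for x in (lam12, lam21, lam13, lam24, lam34, lam43, dt)))
    shape = lam12.shape
    A = np.zeros(shape + (2, 2))
    A[..., 0, 0] = -(lam12 + lam13)
    A[..., 0, 1] = lam12
    A[..., 1, 0] = lam21
    A[..., 1, 1] = -(lam21 + lam24)
    C = np.zeros(shape + (2, 2))
    C[..., 0, 0] = -lam34
    C[..., 0, 1] = lam34
    C[..., 1, 0] = lam43
    C[..., 1, 1] = -lam43

    EA = _expm2_general(A, dt)
    EC = expm_two_state(lam34, lam43, dt)

    # RHS = e^{At} B - B e^{Ct}, with B = diag(lam13, lam24)
    R = np.empty(shape + (2, 2))
    R[..., 0, 0] = EA[..., 0, 0] * lam13 - lam13 * EC[..., 0, 0]
    R[..., 0, 1] = EA[..., 0, 1] * lam24 - lam13 * EC[..., 0, 1]
    R[..., 1, 0] = EA[..., 1, 0] * lam13 - lam24 * EC[..., 1, 0]
    R[..., 1, 1] = EA[..., 1, 1] * lam24 - lam24 * EC[..., 1, 1]

    # M = kron(A, I) - kron(I, C^T) acting on row-major vec(X)
    a11, a12, a21, a22 = A[..., 0, 0], A[..., 0, 1], A[..., 1, 0], A[..., 1, 1]
    c11, c12, c21, c22 = C[..., 0, 0], C[..., 0, 1], C[..., 1, 0], C[..., 1, 1]
    M = np.zeros(shape + (4, 4))
    M[..., 0, 0] = a11 - c11
    M[..., 0, 1] = -c21
    M[..., 0, 2] = a12
    M[..., 1, 0] = -c12
    M[..., 1, 1] = a11 - c22
    M[..., 1, 3] = a12
    M[..., 2, 0] = a21
    M[..., 2, 2] = a22 - c11
    M[..., 2, 3] = -c21
    M[..., 3, 1] = a21
    M[..., 3, 2] = -c12
    M[..., 3, 3] = a22 - c22
    rhs = R.reshape(shape + (4,))

    # conditioning check: singular when spec(A) meets spec(C); eigenvalues of
    # both 2x2 blocks are closed form, so check the minimum spectral gap
    tauA = 0.5 * (a11 + a22)
    dA = np.sqrt(np.maximum(0.25 * (a11 - a22) ** 2 + a12 * a21, 0.0))
    tauC = 0.5 * (c11 + c22)
    dC = np.sqrt(np.maximum(0.25 * (c11 - c22) ** 2 + c12 * c21, 0.0))
    scale = 1.0 + np.abs(tauA) + np.abs(tauC)
    gap = np.minimum(
        np.minimum(np.abs((tauA + dA) - (tauC + dC)), np.abs((tauA + dA) - (tauC - dC))),
        np.minimum(np.abs((tauA - dA) - (tauC + dC)), np.abs((tauA - dA) - (tauC - dC))))
    bad = gap < 1e-9 * scale
    M_safe = np.where(bad[..., None, None], np.eye(4), M)
    X = np.linalg.solve(M_safe, rhs[..., None])[..., 0].reshape(shape + (2, 2))

    P = np.zeros(shape + (4, 4))
    P[..., :2, :2] = EA
    P[..., :2, 2:] = X
    P[..., 2:, 2:] = EC

    if np.any(bad):
        flat = P.reshape(-1, 4, 4)
        rates = [x.reshape(-1) for x in (lam12, lam21, lam13, lam24, lam34, lam43, dt)]
        # overflow inside scipy's squaring at extreme rates yields non-finite
        # entries; they propagate as NaN and are rejected by the caller
        with np.errstate(over="ignore", invalid="ignore"):
            for idx in np.nonzero(bad.reshape(-1))[0]:
                l12, l21, l13, l24, l34, l43, d = (r[idx] for r in rates)
                Q = np.array([
                    [-(l12 + l13), l12, l13, 0.0],
                    [l21, -(l21 + l24), 0.0, l24],
                    [0.0, 0.0, -l34, l34],
                    [0.0, 0.0, l43, -l43],
                ])
                flat[idx] = _scipy_expm(Q * d)
        P = flat.reshape(shape + (4, 4))
    # floating-point hygiene: clamp tiny negatives, renormalise rows
    # (NaN rows from an overflowed fallback propagate for the caller to catch)
    with np.errstate(invalid="ignore"):
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=-1, keepdims=True)
    return P


def expm_mover3(lam12, lam21, lam13, lam23, dt):
    """Transition probabilities for the 3-state mover chain (absorbing damage).

    The transient 2x2 block exponential is closed form; the damage column is
    the complement of the row sums.
    """
    lam12, lam21, lam13, lam23, dt = np.broadcast_arrays(
        *(np.asarray(x, dtype=float) for x in (lam12, lam21, lam13, lam23, dt)))
    shape = lam12.shape
    A = np.zeros(shape + (2, 2))
    A[..., 0, 0] = -(lam12 + lam13)
    A[..., 0, 1] = lam12
    A[..., 1, 0] = lam21
    A[..., 1, 1] = -(lam21 + lam23)
    EA = _expm2_general(A, dt)
    P = np.zeros(shape + (3, 3))
    P[..., :2, :2] = EA
    P[..., 0, 2] = 1.0 - EA[..., 0, :].sum(axis=-1)
    P[..., 1, 2] = 1.0 - EA[..., 1, :].sum(axis=-1)
    P[..., 2, 2] = 1.0
    np.clip(P, 0.0, None, out=P)
    P /= P.sum(axis=-1, keepdims=True)
    return P
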