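"""Compiled inner loops for the marginal likelihood.

Each kernel evaluates, for every quadrature node pair, the closed-form
transition-probability entries of the conditional chain on the unique
(covariate, interval-length) rows, gathers the entry each observed joint
transition needs, and accumulates log-probabilities per group (interval or
patient).  The closed forms mirror :mod:`jointmsm.markov`: 2x2 block
exponentials via their (nonpositive, real) eigenvalues plus a 4x4 Gaussian
elimination for the Sylvester block of the six-state mover chain.

If numba is unavailable the evaluator falls back to the vectorised numpy
path; rows whose activity blocks have (numerically) coincident spectra are
flagged so the caller can recompute with the robust matrix exponential.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit, prange
    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a soft dependency
    HAVE_NUMBA = False

    def njit(*a, **k):
        def wrap(f):
            return f
        return wrap if not (len(a) == 1 and callable(a[0])) else a[0]

    prange = range

_CLIP = 60.0


@njit(cache=True, inline="always", fastmath=True)
def _cexp(x):
    if x > _CLIP:
        x = _CLIP
    elif x < -_CLIP:
        x = -_CLIP
    return np.exp(x)


@njit(cache=True, inline="always", fastmath=True)
def _expm2(a11, a12, a21, a22, dt, out):
    """exp(t*[[a11,a12],[a21,a22]]) for real spectrum with eigenvalues <= 0."""
    tau = 0.5 * (a11 + a22)
    disc = 0.25 * (a11 - a22) ** 2 + a12 * a21
    d = np.sqrt(disc) if disc > 0.0 else 0.0
    # tau + d <= 0 mathematically; clamp cancellation noise at huge rates
    tpd = tau + d
    if tpd > 0.0:
        tpd = 0.0
    ep = np.exp(tpd * dt)
    em = np.exp((tau - d) * dt)
    ch = 0.5 * (ep + em)
    x = d * dt
    if x < 1e-6:
        f = dt * np.exp(tau * dt) * (1.0 + x * x / 6.0)
    else:
        f = (ep - em) / (2.0 * d)
    out[0, 0] = ch + f * (a11 - tau)
    out[0, 1] = f * a12
    out[1, 0] = f * a21
    out[1, 1] = ch + f * (a22 - tau)


@njit(cache=True, inline="always", fastmath=True)
def _solve4(M, b):
    """In-place Gaussian elimination with partial pivoting; returns the
    smallest pivot magnitude encountered (conditioning signal)."""
    minpiv = 1e308
    for col in range(4):
        piv = col
        best = abs(M[col, col])
        for r in range(col + 1, 4):
            if abs(M[r, col]) > best:
                best = abs(M[r, col])
                piv = r
        if piv != col:
            for c in range(4):
                tmp = M[col, c]
                M[col, c] = M[piv, c]
                M[piv, c] = tmp
            tmp = b[col]
            b[col] = b[piv]
            b[piv] = tmp
        if best < minpiv:
            minpiv = best
        if best == 0.0:
            return 0.0
        inv = 1.0 / M[col, col]
        for r in range(col + 1, 4):
            factor = M[r, col] * inv
            if factor != 0.0:
                for c in range(col, 4):
                    M[r, c] -= factor * M[col, c]
                b[r] -= factor * b[col]
    for col in range(3, -1, -1):
        s = b[col]
        for c in range(col + 1, 4):
            s -= M[col, c] * b[c]
        b[col] = s / M[col, col]
    return minpiv


@njit(cache=True, parallel=True, fastmath=True)
def mover6_group_ll(e12, e21, e13, alpha, bd1, bd2, ba, U, V, udt,
                    inv, frm, to, group, n_groups, out):
    """Six-state mover chain: out[group, pair] += log P[frm, to].

    Returns the number of (pair, unique-row) combinations whose Sylvester
    system was ill conditioned (caller should fall back if > 0).
    """
    n_unique = e12.shape[0]
    n_rows = inv.shape[0]
    n_pairs = U.shape[0]
    ebd1 = np.exp(bd1)
    ebd2 = np.exp(bd2)
    eba = np.exp(ba)
    bad_total = 0
    for p in prange(n_pairs):
        P = np.empty((n_unique, 4, 4))
        EA = np.empty((2, 2))
        EC = np.empty((2, 2))
        M = np.empty((4, 4))
        rhs = np.empty(4)
        bad = 0
        for iu in range(n_unique):
            l12 = _cexp(e12[iu] + U[p])
            l21 = _cexp(e21[iu] + alpha * U[p])
            l13 = _cexp(e13[iu] + V[p])
            l24 = l13 * eba
            l34 = l12 * ebd1
            l43 = l21 * ebd2
            dt = udt[iu]
            a11 = -(l12 + l13); a12 = l12
            a21 = l21; a22 = -(l21 + l24)
            c11 = -l34; c12 = l34
            c21 = l43; c22 = -l43
            _expm2(a11, a12, a21, a22, dt, EA)
            _expm2(c11, c12, c21, c22, dt, EC)
            # Sylvester system for the transient->damaged block
            M[0, 0] = a11 - c11; M[0, 1] = -c21;      M[0, 2] = a12;       M[0, 3] = 0.0
            M[1, 0] = -c12;      M[1, 1] = a11 - c22; M[1, 2] = 0.0;       M[1, 3] = a12
            M[2, 0] = a21;       M[2, 1] = 0.0;       M[2, 2] = a22 - c11; M[2, 3] = -c21
            M[3, 0] = 0.0;       M[3, 1] = a21;       M[3, 2] = -c12;      M[3, 3] = a22 - c22
            rhs[0] = EA[0, 0] * l13 - l13 * EC[0, 0]
            rhs[1] = EA[0, 1] * l24 - l13 * EC[0, 1]
            rhs[2] = EA[1, 0] * l13 - l24 * EC[1, 0]
            rhs[3] = EA[1, 1] * l24 - l24 * EC[1, 1]
            scale = 1.0 + l12 + l21 + l13 + l24 + l34 + l43
            piv = _solve4(M, rhs)
            if piv < 1e-9 * scale:
                bad += 1
            for i in range(2):
                for j in range(2):
                    P[iu, i, j] = EA[i, j]
                    P[iu, i, 2 + j] = rhs[2 * i + j]
                    P[iu, 2 + i, j] = 0.0
                    P[iu, 2 + i, 2 + j] = EC[i, j]
            # clamp and renormalise rows
            for i in range(4):
                s = 0.0
                for j in range(4):
                    if P[iu, i, j] < 0.0:
                        P[iu, i, j] = 0.0
                    s += P[iu, i, j]
                if s > 0.0:
                    for j in range(4):
                        P[iu, i, j] /= s
        acc = np.zeros(n_groups)
        for r in range(n_rows):
            pe = P[inv[r], frm[r], to[r]]
            if pe < 1e-300:
                pe = 1e-300
            acc[group[r]] += np.log(pe)
        for g in range(n_groups):
            out[g, p] = acc[g]
        bad_total += bad
    return bad_total


@njit(cache=True, parallel=True, fastmath=True)
def mover5_group_ll(c1, c2, c3, c4, alpha1, alpha2, U, V, udt,
                    inv, frm, to, group, n_groups, out):
    """Five-state (3-state mover) chain: out[group, pair] += log P[frm, to]."""
    n_unique = c1.shape[0]
    n_rows = inv.shape[0]
    n_pairs = U.shape[0]
    for p in prange(n_pairs):
        P = np.empty((n_unique, 3, 3))
        EA = np.empty((2, 2))
        for iu in range(n_unique):
            inv_mu1 = _cexp(-(c1[iu] + U[p]))
            inv_mu2 = _cexp(-(c2[iu] + alpha1 * U[p]))
            lo13 = c3[iu] + V[p]
            lo23 = c4[iu] + alpha2 * V[p]
            if lo13 > _CLIP:
                lo13 = _CLIP
            elif lo13 < -_CLIP:
                lo13 = -_CLIP
            if lo23 > _CLIP:
                lo23 = _CLIP
            elif lo23 < -_CLIP:
                lo23 = -_CLIP
            p13 = 1.0 / (1.0 + np.exp(-lo13))
            p23 = 1.0 / (1.0 + np.exp(-lo23))
            l12 = (1.0 - p13) * inv_mu1
            l13 = p13 * inv_mu1
            l21 = (1.0 - p23) * inv_mu2
            l23 = p23 * inv_mu2
            dt = udt[iu]
            _expm2(-(l12 + l13), l12, l21, -(l21 + l23), dt, EA)
            for i in range(2):
                for j in range(2):
                    P[iu, i, j] = EA[i, j] if EA[i, j] > 0.0 else 0.0
            P[iu, 0, 2] = 1.0 - P[iu, 0, 0] - P[iu, 0, 1]
            P[iu, 1, 2] = 1.0 - P[iu, 1, 0] - P[iu, 1, 1]
            if P[iu, 0, 2] < 0.0:
                P[iu, 0, 2] = 0.0
            if P[iu, 1, 2] < 0.0:
                P[iu, 1, 2] = 0.0
            P[iu, 2, 0] = 0.0
            P[iu, 2, 1] = 0.0
            P[iu, 2, 2] = 1.0
        acc = np.zeros(n_groups)
        for r in range(n_rows):
            pe = P[inv[r], frm[r], to[r]]
            if pe < 1e-300:
                pe = 1e-300
            acc[group[r]] += np.log(pe)
        for g in range(n_groups):
            out[g, p] = acc[g]
    return 0
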