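"""Generator construction, matrix exponentials and the sojourn/jump bijection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp
from scipy.linalg import expm as scipy_expm

from jointmsm.markov import (FIVE_MOVER, FIVE_STAYER, SIX_MOVER, SIX_STAYER,
                             SojournJump, build_generator, expm_mover3,
                             expm_mover4, expm_two_state, get_space,
                             intensities_to_sojourn_jump,
                             sojourn_jump_to_intensities, transition_matrix)

rates = st.floats(min_value=0.0, max_value=5.0, allow_nan=False)
pos_rates = st.floats(min_value=1e-3, max_value=5.0, allow_nan=False)


def ode_transition_matrix(Q, dt, rtol=1e-10, atol=1e-12):
    """Independent oracle: integrate the Kolmogorov forward equations
    dP/dt = P Q from P(0) = I with adaptive Runge-Kutta."""
    n = Q.shape[0]
    sol = solve_ivp(lambda t, p: (p.reshape(n, n) @ Q).ravel(), (0.0, dt),
                    np.eye(n).ravel(), rtol=rtol, atol=atol, dense_output=False)
    return sol.y[:, -1].reshape(n, n)


def random_mover_generator(rng):
    lam = {t: rng.uniform(0.01, 3.0) for t in SIX_MOVER.transitions}
    return build_generator(lam, SIX_MOVER)


class TestBuildGenerator:
    def test_zero_rates_give_zero_matrix(self):
        Q = build_generator({}, SIX_MOVER)
        assert np.array_equal(Q, np.zeros((4, 4)))

    def test_row_is_rates_with_negative_sum_diagonal(self):
        Q = build_generator({(1, 2): 1.0, (1, 3): 0.5}, SIX_MOVER)
        assert np.allclose(Q[0], [-1.5, 1.0, 0.5, 0.0])

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError, match=">= 0"):
            build_generator({(1, 2): -0.1}, SIX_MOVER)

    def test_disallowed_transition_rejected(self):
        # damage is irreversible: 3 -> 1 does not exist
        with pytest.raises(ValueError, match="not allowed"):
            build_generator({(3, 1): 0.5}, SIX_MOVER)
        with pytest.raises(ValueError, match="not allowed"):
            build_generator({(1, 2): 0.5}, SIX_STAYER)

    @given(st.lists(rates, min_size=6, max_size=6))
    def test_rows_sum_to_zero(self, vals):
        lam = dict(zip(SIX_MOVER.transitions, vals))
        Q = build_generator(lam, SIX_MOVER)
        assert np.abs(Q.sum(axis=1)).max() < 1e-12

    def test_state_space_structure(self):
        assert SIX_MOVER.n_states == 4 and SIX_STAYER.n_states == 2
        assert FIVE_MOVER.n_states == 3 and FIVE_STAYER.n_states == 2
        # no transition leaves a damaged state for an undamaged one
        for r, s in SIX_MOVER.transitions:
            assert not (r in (3, 4) and s in (1, 2))
        assert all(t[0] != 3 for t in FIVE_MOVER.transitions)
        assert get_space("six_state", "mover") is SIX_MOVER


class TestTransitionMatrix:
    def test_zero_interval_is_identity(self):
        Q = build_generator({(1, 2): 1.0}, SIX_MOVER)
        assert np.array_equal(transition_matrix(Q, 0.0), np.eye(4))

    def test_symmetric_two_state_reaches_uniform(self):
        Q = build_generator({(5, 6): 1.0, (6, 5): 1.0}, SIX_STAYER)
        P = transition_matrix(Q, 50.0)
        assert np.abs(P - 0.5).max() < 1e-10

    def test_two_state_closed_form(self):
        # rates 1 and 2 over dt=1: P[1,1] = 2/3 + e^{-3}/3
        Q = build_generator({(5, 6): 1.0, (6, 5): 2.0}, SIX_STAYER)
        P = transition_matrix(Q, 1.0)
        expected = 2.0 / 3.0 + np.exp(-3.0) / 3.0
        assert P[0, 0] == pytest.approx(expected, abs=1e-12)
        assert np.abs(P - ode_transition_matrix(Q, 1.0)).max() < 1e-9

    def test_negative_dt_and_nonfinite_rejected(self):
        Q = build_generator({(1, 2): 1.0}, SIX_MOVER)
        with pytest.raises(ValueError):
            transition_matrix(Q, -0.5)
        with pytest.raises(ValueError):
            transition_matrix(np.full((2, 2), np.nan), 1.0)

    def test_chapman_kolmogorov(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            Q = random_mover_generator(rng)
            s, t = rng.uniform(0, 20, size=2)
            lhs = transition_matrix(Q, s + t)
            rhs = transition_matrix(Q, s) @ transition_matrix(Q, t)
            assert np.abs(lhs - rhs).max() < 1e-8

    def test_agrees_with_ode_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            Q = random_mover_generator(rng)
            dt = rng.uniform(0.05, 8.0)
            assert np.abs(transition_matrix(Q, dt) - ode_transition_matrix(Q, dt)).max() < 1e-7

    def test_damaged_states_cannot_reach_undamaged(self):
        rng = np.random.default_rng(11)
        Q = random_mover_generator(rng)
        P = transition_matrix(Q, 2.5)
        assert np.all(P[2:, :2] == 0.0)

    def test_absorbing_row_is_unit_vector(self):
        Q = build_generator({(1, 2): 0.7, (2, 1): 0.3, (1, 3): 0.2, (2, 3): 0.4},
                            FIVE_MOVER)
        for dt in (0.1, 1.0, 25.0):
            P = transition_matrix(Q, dt)
            assert np.allclose(P[2], [0, 0, 1], atol=1e-14)


class TestFastKernels:
    """The closed-form vectorised exponentials must match the robust expm."""

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_mover4_matches_expm(self, seed):
        rng = np.random.default_rng(seed)
        r = rng.uniform(0.0, 4.0, size=(200, 6))
        dt = rng.uniform(0.01, 10.0, size=200)
        P = expm_mover4(*(r[:, k] for k in range(6)), dt)
        for i in range(200):
            l12, l21, l13, l24, l34, l43 = r[i]
            Q = np.array([[-(l12 + l13), l12, l13, 0],
                          [l21, -(l21 + l24), 0, l24],
                          [0, 0, -l34, l34],
                          [0, 0, l43, -l43]])
            assert np.abs(P[i] - scipy_expm(Q * dt[i])).max() < 1e-10

    def test_mover4_degenerate_spectrum_falls_back(self):
        # lam13 = lam24 = 0 with matching activity rates makes the undamaged
        # and damaged blocks share their spectrum (singular Sylvester system)
        P = expm_mover4(1.0, 2.0, 0.0, 0.0, 1.0, 2.0, 1.5)
        Q = np.array([[-1, 1, 0, 0], [2, -2, 0, 0], [0, 0, -1, 1], [0, 0, 2, -2.0]])
        assert np.abs(P - scipy_expm(Q * 1.5)).max() < 1e-12

    def test_mover3_matches_expm(self):
        rng = np.random.default_rng(5)
        r = rng.uniform(0.0, 4.0, size=(100, 4))
        dt = rng.uniform(0.01, 10.0, size=100)
        P = expm_mover3(*(r[:, k] for k in range(4)), dt)
        for i in range(100):
            l12, l21, l13, l23 = r[i]
            Q = np.array([[-(l12 + l13), l12, l13],
                          [l21, -(l21 + l23), l23],
                          [0.0, 0.0, 0.0]])
            assert np.abs(P[i] - scipy_expm(Q * dt[i])).max() < 1e-10

    def test_two_state_large_rates_stable(self):
        P = expm_two_state(1e8, 2e8, 3.0)
        assert np.allclose(P[0], [2 / 3, 1 / 3])
        assert np.all(np.isfinite(expm_mover4(1e8, 1e7, 1e6, 1e5, 1e4, 1e3, 5.0)))


class TestSojournJumpBijection:
    def test_printed_equations(self):
        sj = SojournJump(mu1=2.0, mu2=1.0, mu4=4.0, mu5=1.0, p13=0.25, p23=0.5)
        lam = sojourn_jump_to_intensities(sj)
        assert lam[(1, 2)] == pytest.approx(0.375)
        assert lam[(1, 3)] == pytest.approx(0.125)
        assert lam[(4, 5)] == pytest.approx(0.25)

    def test_inverse_example(self):
        sj = intensities_to_sojourn_jump({(1, 2): 0.375, (1, 3): 0.125,
                                          (2, 1): 0.3, (2, 3): 0.2,
                                          (4, 5): 0.25, (5, 4): 1.0})
        assert sj.mu1 == pytest.approx(2.0)
        assert sj.p13 == pytest.approx(0.25)
        assert sj.mu4 == pytest.approx(4.0)
        # jump probabilities out of each state sum to one
        assert sj.p13 + (1 - sj.p13) == pytest.approx(1.0)

    @settings(max_examples=200, deadline=None)
    @given(mu1=st.floats(0.05, 50), mu2=st.floats(0.05, 50),
           mu4=st.floats(0.05, 50), mu5=st.floats(0.05, 50),
           p13=st.floats(1e-4, 1 - 1e-4), p23=st.floats(1e-4, 1 - 1e-4))
    def test_round_trip_is_identity(self, mu1, mu2, mu4, mu5, p13, p23):
        sj = SojournJump(mu1, mu2, mu4, mu5, p13, p23)
        back = intensities_to_sojourn_jump(sojourn_jump_to_intensities(sj))
        for f in ("mu1", "mu2", "mu4", "mu5", "p13", "p23"):
            assert getattr(back, f) == pytest.approx(getattr(sj, f), rel=1e-12)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError, match="> 0"):
            sojourn_jump_to_intensities(SojournJump(-1, 1, 1, 1, 0.5, 0.5))
        with pytest.raises(ValueError, match="strictly in"):
            sojourn_jump_to_intensities(SojournJump(1, 1, 1, 1, 1.0, 0.5))
        with pytest.raises(ValueError, match="state 1"):
            intensities_to_sojourn_jump({(1, 2): 0.0, (1, 3): 0.0,
                                         (2, 1): 1.0, (2, 3): 1.0,
                                         (4, 5): 1.0, (5, 4): 1.0})
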