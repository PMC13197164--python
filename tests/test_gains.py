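"""Nash and decoupled gain solvers against independent LQR oracles."""

import numpy as np
import pytest

from dyadreach import (
    Condition,
    ModelParams,
    SolverError,
    build_costs,
    build_dynamics,
    get_hypothesis,
    solve_decoupled_gains,
    solve_gains,
    solve_nash_gains,
)
from dyadreach.costs import CostSpec
from dyadreach.dynamics import DynamicsSpec, IX_CCX

from conftest import random_game


# --- independent oracles (plain backward recursions, written from scratch) --

def oracle_lqr(A, B, Q, QT, R, N):
    """Textbook finite-horizon LQR recursion."""
    P = QT
    F = [None] * N
    for k in range(N - 1, -1, -1):
        F[k] = np.linalg.solve(R + B.T @ P @ B, B.T @ P @ A)
        Acl = A - B @ F[k]
        P = Q + F[k].T @ R @ F[k] + Acl.T @ P @ Acl
    return np.array(F)


def oracle_best_response(A, B_self, B_other, F_other, Q, QT, R_self,
                         R_other, alpha, N):
    """Optimal LQR response to a frozen partner policy.

    The partner's policy is folded into the plant (A - B_other F_other)
    and the alpha-weighted partner control cost into the state cost.
    """
    P = QT
    F = [None] * N
    for k in range(N - 1, -1, -1):
        Ak = A - B_other @ F_other[k]
        Qk = Q + alpha * F_other[k].T @ R_other @ F_other[k]
        F[k] = np.linalg.solve(R_self + B_self.T @ P @ B_self,
                               B_self.T @ P @ Ak)
        Acl = Ak - B_self @ F[k]
        P = Qk + F[k].T @ R_self @ F[k] + Acl.T @ P @ Acl
    return np.array(F)


def _specs(A, B1, B2, Q1T, Q2T, R1, R2, a1, a2):
    n = A.shape[0]
    Qz = np.zeros((n, n))
    dyn = DynamicsSpec(A=A, B1=B1, B2=B2, time_step=0.01, delay_steps=0)
    c1 = CostSpec(Q_running=Qz, Q_terminal=Q1T, R=R1, alpha=a1)
    c2 = CostSpec(Q_running=Qz, Q_terminal=Q2T, R=R2, alpha=a2)
    return dyn, c1, c2


# ---------------------------------------------------------------------------

def test_each_gain_is_best_response_on_random_games(rng):
    """Nash property: F1 (F2) is optimal against the frozen partner policy."""
    N = 8
    for _ in range(20):
        game = random_game(rng)
        A, B1, B2, Q1T, Q2T, R1, R2, a1, a2 = game
        dyn, c1, c2 = _specs(*game)
        g = solve_nash_gains(dyn, c1, c2, N)
        Qz = np.zeros_like(A)
        br1 = oracle_best_response(A, B1, B2, g.F2, Qz,
                                   Q1T + a1 * Q2T, R1, R2, a1, N)
        br2 = oracle_best_response(A, B2, B1, g.F1, Qz,
                                   Q2T + a2 * Q1T, R2, R1, a2, N)
        np.testing.assert_allclose(g.F1, br1, atol=1e-8)
        np.testing.assert_allclose(g.F2, br2, atol=1e-8)


def test_game_with_inert_partner_reduces_to_lqr(rng):
    """With B2 = 0 and alpha = 0 the game is a single-player LQR problem."""
    N = 10
    A, B1, B2, Q1T, Q2T, R1, R2, _, _ = random_game(rng)
    game = (A, B1, np.zeros_like(B2), Q1T, Q2T, R1, R2, 0.0, 0.0)
    dyn, c1, c2 = _specs(*game)
    g = solve_nash_gains(dyn, c1, c2, N)
    ref = oracle_lqr(A, B1, np.zeros_like(A), Q1T, R1, N)
    np.testing.assert_allclose(g.F1, ref, atol=1e-12)


def test_symmetric_scalar_toy_game_has_equal_gains():
    A = np.array([[1.0]])
    B = np.array([[1.0]])
    Q = np.array([[1.0]])
    dyn = DynamicsSpec(A=A, B1=B, B2=B, time_step=1.0, delay_steps=0)
    c = CostSpec(Q_running=Q, Q_terminal=Q, R=np.array([[1.0]]), alpha=0.0)
    g = solve_nash_gains(dyn, c, c, 2)
    np.testing.assert_allclose(g.F1, g.F2, atol=1e-12)


def test_toy_game_matches_alternating_best_response_limit():
    """The Nash solution is the limit of alternating best-response solves."""
    A = np.array([[1.0]])
    B = np.array([[1.0]])
    Q = np.array([[1.0]])
    R = np.array([[1.0]])
    N = 2
    dyn = DynamicsSpec(A=A, B1=B, B2=B, time_step=1.0, delay_steps=0)
    c = CostSpec(Q_running=Q, Q_terminal=Q, R=R, alpha=0.0)
    g = solve_nash_gains(dyn, c, c, N)
    F2 = np.zeros((N, 1, 1))
    for _ in range(200):
        F1 = oracle_best_response(A, B, B, F2, Q, Q, R, R, 0.0, N)
        F2 = oracle_best_response(A, B, B, F1, Q, Q, R, R, 0.0, N)
    np.testing.assert_allclose(g.F1, F1, atol=1e-8)
    np.testing.assert_allclose(g.F2, F2, atol=1e-8)


def test_decoupled_equals_nash_with_partner_input_zeroed(fast_params):
    cond = Condition(True, True)
    hyp = get_hypothesis("rep_weighted")
    dyn = build_dynamics(fast_params)
    c1, c2 = build_costs(cond, get_hypothesis("no_rep_self"), fast_params)
    F1_dec = solve_decoupled_gains(dyn, c1, fast_params.horizon_steps)
    dyn0 = DynamicsSpec(A=dyn.A, B1=dyn.B1, B2=np.zeros_like(dyn.B2),
                        time_step=dyn.time_step, delay_steps=dyn.delay_steps)
    g0 = solve_nash_gains(dyn0, c1, c2, fast_params.horizon_steps)
    np.testing.assert_allclose(F1_dec, g0.F1, atol=1e-10)


def test_decoupled_and_nash_self_gains_differ_when_partner_matters(fast_params):
    """A relevant partner target changes the Nash self gains."""
    dyn = build_dynamics(fast_params)
    cond = Condition(self_relevant=False, partner_relevant=True)
    c1, c2 = build_costs(cond, get_hypothesis("rep_self"), fast_params)
    F1_dec = solve_decoupled_gains(dyn, c1, fast_params.horizon_steps)
    g = solve_nash_gains(dyn, c1, c2, fast_params.horizon_steps)
    assert np.abs(g.F1 - F1_dec).max() > 1e-3


def test_irrelevant_targets_give_negligible_lateral_gains(fast_params):
    """With both targets wide, neither player corrects laterally."""
    dyn = build_dynamics(fast_params)
    mid = fast_params.horizon_steps // 2
    gains = {}
    for label in ("pi/si", "pr/sr"):
        g = solve_gains(dyn, Condition.from_label(label),
                        get_hypothesis("no_rep_self"), fast_params)
        gains[label] = abs(g.F1[mid, 0, IX_CCX])
    assert gains["pi/si"] < 0.05 * gains["pr/sr"]


def test_lateral_gain_grows_with_terminal_weight(fast_params):
    """Raising the relevant terminal weight strengthens lateral feedback."""
    mags = []
    for w in (100.0, 2_000.0, 40_000.0):
        p = fast_params.with_(terminal_weight_relevant=w)
        dyn = build_dynamics(p)
        g = solve_gains(dyn, Condition(True, True),
                        get_hypothesis("rep_weighted"), p)
        mags.append(abs(g.F1[p.horizon_steps // 2, 0, IX_CCX]))
    assert mags[0] < mags[1] < mags[2]


def test_nonconvergence_raises_solver_error(rng):
    game = random_game(rng)
    dyn, c1, c2 = _specs(*game)
    with pytest.raises(SolverError, match="residual"):
        solve_nash_gains(dyn, c1, c2, 5, max_iter=1)
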