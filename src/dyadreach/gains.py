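"""Feedback-gain solvers: finite-horizon LQR and coupled-Riccati Nash.

Both players apply linear state feedback on their own state estimate,
``u_i = -F_{i,k} x_hat_i``.  Under a partner representation the pair of
gain sequences is the Nash equilibrium of the linear-quadratic game: at
every step each player's gain is the optimal response to the other player's
gain with the alpha-weighted partner cost folded into its own objective.
The equilibrium at each backward step is found by damped fixed-point
iteration on the pair of best-response maps, warm-started from the
previous step's solution.  Without a partner representation each player
solves a single-player LQR assuming the partner never acts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .costs import CostSpec, build_costs
from .dynamics import DynamicsSpec, build_dynamics
from .params import Condition, Hypothesis, ModelParams


class SolverError(RuntimeError):
    """Raised when the coupled fixed point fails to converge."""


@dataclass(frozen=True)
class FeedbackGains:
    """Time-indexed gain sequences for both players.

    ``F1``/``F2`` have shape (horizon_steps, n_control, n_aug).  The
    ``partner_representation`` flag records whether the pair is a Nash
    solution (True) or two decoupled single-player solutions (False); the
    simulator uses it to decide how each estimator predicts the partner's
    command.
    """

    F1: np.ndarray
    F2: np.ndarray
    partner_representation: bool

    @property
    def horizon_steps(self) -> int:
        return self.F1.shape[0]


def lqr_gains(A: np.ndarray, B: np.ndarray, Q_running: np.ndarray,
              Q_terminal: np.ndarray, R: np.ndarray,
              horizon_steps: int) -> np.ndarray:
    """Finite-horizon discrete LQR gain sequence (backward recursion)."""
    n, m = B.shape
    F = np.empty((horizon_steps, m, n))
    P = Q_terminal.copy()
    for k in range(horizon_steps - 1, -1, -1):
        S = B.T @ P                                   # m x n
        Fk = np.linalg.solve(R + S @ B, S @ A)
        Acl = A - B @ Fk
        P = Q_running + Fk.T @ R @ Fk + Acl.T @ P @ Acl
        P = 0.5 * (P + P.T)
        F[k] = Fk
    return F


def solve_decoupled_gains(dyn: DynamicsSpec, cost1: CostSpec,
                          horizon_steps: int, *, player: int = 1) -> np.ndarray:
    """Single-player LQR gains computed as if the partner never acts.

    Equivalent to the Nash solution of the game with the partner's input
    matrix zeroed.  Returns only this player's gain sequence.
    """
    B = dyn.B1 if player == 1 else dyn.B2
    return lqr_gains(dyn.A, B, cost1.Q_running, cost1.Q_terminal, cost1.R,
                     horizon_steps)


def solve_nash_gains(dyn: DynamicsSpec, cost1: CostSpec, cost2: CostSpec,
                     horizon_steps: int, *, tol: float = 1e-10,
                     max_iter: int = 500, damping: float = 1.0) -> FeedbackGains:
    """Nash-equilibrium gain sequences of the two-player LQ game.

    Backward recursion from the joint terminal costs.  At each step the
    pair (F1_k, F2_k) solves the coupled stationarity conditions

        F1 = (R1 + B1' P1 B1)^-1 B1' P1 (A - B2 F2)
        F2 = (R2 + B2' P2 B2)^-1 B2' P2 (A - B1 F1)

    where P_i is player i's joint-cost value matrix from step k+1.  The
    fixed point is iterated (optionally damped) to ``tol`` on the maximum
    gain change, warm-started from the previous step.
    """
    A, B1, B2 = dyn.A, dyn.B1, dyn.B2
    n = dyn.n_aug
    m = dyn.n_control
    R1, R2 = cost1.R, cost2.R
    a1, a2 = cost1.alpha, cost2.alpha
    Q1r = cost1.joint_running(cost2)
    Q2r = cost2.joint_running(cost1)
    P1 = cost1.joint_terminal(cost2)
    P2 = cost2.joint_terminal(cost1)
    F1 = np.empty((horizon_steps, m, n))
    F2 = np.empty((horizon_steps, m, n))
    F1k = np.zeros((m, n))
    F2k = np.zeros((m, n))
    for k in range(horizon_steps - 1, -1, -1):
        S1 = B1.T @ P1                      # m x n
        S2 = B2.T @ P2
        M1 = R1 + S1 @ B1                   # m x m
        M2 = R2 + S2 @ B2
        S1A, S2A = S1 @ A, S2 @ A
        S1B2, S2B1 = S1 @ B2, S2 @ B1
        resid = np.inf
        for _ in range(max_iter):
            F1new = np.linalg.solve(M1, S1A - S1B2 @ F2k)
            F2new = np.linalg.solve(M2, S2A - S2B1 @ F1new)
            if damping != 1.0:
                F1new = damping * F1new + (1 - damping) * F1k
                F2new = damping * F2new + (1 - damping) * F2k
            resid = max(np.max(np.abs(F1new - F1k)), np.max(np.abs(F2new - F2k)))
            F1k, F2k = F1new, F2new
            if resid < tol:
                break
        else:
            raise SolverError(
                f"coupled fixed point did not converge at step {k}: "
                f"residual {resid:.3e} after {max_iter} iterations"
            )
        Acl = A - B1 @ F1k - B2 @ F2k
        P1 = (Q1r + F1k.T @ R1 @ F1k + a1 * (F2k.T @ R2 @ F2k)
              + Acl.T @ P1 @ Acl)
        P2 = (Q2r + F2k.T @ R2 @ F2k + a2 * (F1k.T @ R1 @ F1k)
              + Acl.T @ P2 @ Acl)
        P1 = 0.5 * (P1 + P1.T)
        P2 = 0.5 * (P2 + P2.T)
        F1[k] = F1k
        F2[k] = F2k
    return FeedbackGains(F1=F1, F2=F2, partner_representation=True)


def solve_gains(dyn: DynamicsSpec, condition: Condition,
                hypothesis: Hypothesis, params: ModelParams) -> FeedbackGains:
    """Gain pair for a condition under a policy hypothesis.

    With a partner representation the pair is the Nash solution; without
    one, each player's gains are the decoupled LQR solution under the
    assumption that the partner's gains are zero.
    """
    cost1, cost2 = build_costs(condition, hypothesis, params)
    N = params.horizon_steps
    if hypothesis.partner_representation:
        return solve_nash_gains(dyn, cost1, cost2, N)
    F1 = solve_decoupled_gains(dyn, cost1, N, player=1)
    F2 = solve_decoupled_gains(dyn, cost2, N, player=2)
    return FeedbackGains(F1=F1, F2=F2, partner_representation=False)


def solve_gains_cached(condition_label: str, hypothesis_label: str,
                       params: ModelParams | None = None) -> FeedbackGains:
    """Memoized gain solve keyed by labels and parameter values."""
    from .params import get_hypothesis
    params = params or ModelParams()
    key = (condition_label, hypothesis_label, params)
    if key not in _GAIN_CACHE:
        dyn = build_dynamics(params)
        _GAIN_CACHE[key] = solve_gains(dyn, Condition.from_label(condition_label),
                                       get_hypothesis(hypothesis_label), params)
    return _GAIN_CACHE[key]


_GAIN_CACHE: dict = {}
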