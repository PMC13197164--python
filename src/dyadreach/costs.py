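"""Quadratic cost structures for the two-player reaching game.

Each player ``i`` carries an individual finite-horizon cost

    J_i = 1/2 * sum_k u_i' R_ii u_i  +  1/2 * x_N' Q_{i,N} x_N

with all accuracy pressure in the terminal state cost: the lateral
center-cursor-minus-target error is weighted 40,000 when player i's target
is narrow (task-relevant) and 100 when it is wide (task-irrelevant); the
forward error always carries the relevant weight because the targets are
short in the forward dimension.  Small terminal weights on the player's own
hand velocity and muscle force make the solution stabilize at the target.
The joint cost used for control is ``J_i + alpha_i * J_j``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import (
    BASE_DIM,
    IDX_F1,
    IDX_F2,
    IDX_V1,
    IDX_V2,
    IX_CCX,
    IX_CCY,
    IX_TX,
    IX_TY,
)
from .params import Condition, Hypothesis, ModelParams


@dataclass(frozen=True)
class CostSpec:
    """One player's cost matrices on the augmented state.

    ``Q_running`` is zero by default (accuracy is only scored at the final
    step); ``R`` is positive definite and applies every step.
    """

    Q_running: np.ndarray
    Q_terminal: np.ndarray
    R: np.ndarray
    alpha: float

    def joint_terminal(self, other: "CostSpec") -> np.ndarray:
        """Terminal matrix of the joint cost J_i + alpha_i J_j."""
        return self.Q_terminal + self.alpha * other.Q_terminal

    def joint_running(self, other: "CostSpec") -> np.ndarray:
        return self.Q_running + self.alpha * other.Q_running


def _error_penalty(n: int, i: int, j: int, weight: float) -> np.ndarray:
    """Quadratic form weight * (x_i - x_j)^2 as an n x n PSD matrix."""
    Q = np.zeros((n, n))
    Q[i, i] = weight
    Q[j, j] = weight
    Q[i, j] = Q[j, i] = -weight
    return Q


def terminal_cost(relevant: bool, params: ModelParams, n_aug: int,
                  player: int) -> np.ndarray:
    """Terminal state cost for one player on the augmented state.

    Penalizes the center-cursor-vs-target error (lateral weight set by the
    player's target relevance, forward weight fixed) plus small regularizers
    on the player's own hand velocity and muscle force.  Only the current
    base block is scored; history slots carry no cost.
    """
    w_lat = (params.terminal_weight_relevant if relevant
             else params.terminal_weight_irrelevant)
    Q = np.zeros((n_aug, n_aug))
    Q += _error_penalty(n_aug, IX_CCX, IX_TX, w_lat)
    Q += _error_penalty(n_aug, IX_CCY, IX_TY, params.terminal_weight_forward)
    v_idx = IDX_V1 if player == 1 else IDX_V2
    f_idx = IDX_F1 if player == 1 else IDX_F2
    for k in range(v_idx.start, v_idx.stop):
        Q[k, k] += params.terminal_weight_velocity
    for k in range(f_idx.start, f_idx.stop):
        Q[k, k] += params.terminal_weight_force
    return Q


def build_costs(condition: Condition, hypothesis: Hypothesis,
                params: ModelParams) -> tuple[CostSpec, CostSpec]:
    """Cost structures for player 1 (self) and player 2 (partner).

    Player 1's terminal lateral weight follows ``condition.self_relevant``
    and player 2's follows ``condition.partner_relevant``; both players use
    the hypothesis' joint-cost weight alpha.
    """
    if not isinstance(condition, Condition):
        condition = Condition.from_label(str(condition))
    n_aug = BASE_DIM * (params.delay_steps + 1)
    R = params.control_weight * np.eye(2)
    Qz = np.zeros((n_aug, n_aug))
    c1 = CostSpec(
        Q_running=Qz,
        Q_terminal=terminal_cost(condition.self_relevant, params, n_aug, player=1),
        R=R,
        alpha=hypothesis.alpha,
    )
    c2 = CostSpec(
        Q_running=Qz,
        Q_terminal=terminal_cost(condition.partner_relevant, params, n_aug, player=2),
        R=R,
        alpha=hypothesis.alpha,
    )
    return c1, c2
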