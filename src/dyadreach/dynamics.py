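"""Discrete-time state-space dynamics of the two-player reaching game.

The base state stacks, for each hand, planar position, velocity, and muscle
force, followed by the center-cursor position (midpoint-velocity integral of
the two hands) and the target position:

    x = [p1, v1, f1, p2, v2, f2, p_cc, p_target]   (16 scalars, x/y pairs)

Each hand is a point mass ``m`` with viscous drag ``b`` driven by a muscle
force that follows the control signal through a first-order filter with time
constant ``tau``:

    m * dv/dt = -b * v + f
    tau * df/dt = u - f
    d(p_cc)/dt = (v1 + v2) / 2

To expose delayed sensory feedback, the state is augmented with the last
``n_delay`` copies of the base block, so the augmented dimension is
``16 * (n_delay + 1)`` and the transition matrix shifts each base block one
slot down the history each step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import cont2discrete

BASE_DIM = 16

# index layout within the 16-dim base block (x, y interleaved per quantity)
IDX_P1 = slice(0, 2)
IDX_V1 = slice(2, 4)
IDX_F1 = slice(4, 6)
IDX_P2 = slice(6, 8)
IDX_V2 = slice(8, 10)
IDX_F2 = slice(10, 12)
IDX_CC = slice(12, 14)
IDX_TARGET = slice(14, 16)

# lateral (x) components
IX_P1X, IX_V1X, IX_F1X = 0, 2, 4
IX_P2X, IX_V2X, IX_F2X = 6, 8, 10
IX_CCX, IX_CCY = 12, 13
IX_TX, IX_TY = 14, 15


@dataclass(frozen=True)
class DynamicsSpec:
    """Augmented-state transition and input matrices.

    ``A`` acts on the augmented state; ``B1``/``B2`` inject each player's
    two-dimensional control signal into that player's muscle-force rows of
    the current base block only.
    """

    A: np.ndarray
    B1: np.ndarray
    B2: np.ndarray
    time_step: float
    delay_steps: int

    @property
    def n_aug(self) -> int:
        return self.A.shape[0]

    @property
    def n_control(self) -> int:
        return self.B1.shape[1]

    def channel_modified(self) -> "DynamicsSpec":
        """B matrices with the lateral (x) force entries zeroed.

        Models a force channel: neither player's control can produce
        lateral muscle force, so the hands (and hence the center cursor)
        can only move in the forward dimension.
        """
        B1 = self.B1.copy()
        B2 = self.B2.copy()
        B1[IX_F1X, :] = 0.0
        B2[IX_F2X, :] = 0.0
        return DynamicsSpec(self.A, B1, B2, self.time_step, self.delay_steps)


def _base_continuous(params) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Continuous-time (A, B1, B2) on the 16-dim base block."""
    m, b, tau = params.hand_mass, params.viscosity, params.muscle_time_constant
    A = np.zeros((BASE_DIM, BASE_DIM))
    B1 = np.zeros((BASE_DIM, 2))
    B2 = np.zeros((BASE_DIM, 2))
    for d in range(2):  # x, y
        p1, v1, f1 = 0 + d, 2 + d, 4 + d
        p2, v2, f2 = 6 + d, 8 + d, 10 + d
        cc = 12 + d
        A[p1, v1] = 1.0
        A[v1, v1] = -b / m
        A[v1, f1] = 1.0 / m
        A[f1, f1] = -1.0 / tau
        A[p2, v2] = 1.0
        A[v2, v2] = -b / m
        A[v2, f2] = 1.0 / m
        A[f2, f2] = -1.0 / tau
        A[cc, v1] = 0.5
        A[cc, v2] = 0.5
        B1[f1, d] = 1.0 / tau
        B2[f2, d] = 1.0 / tau
    # target rows are zero: the target is constant under the dynamics
    return A, B1, B2


def build_dynamics(params, *, discretization: str = "euler") -> DynamicsSpec:
    """Build the augmented discrete-time dynamics.

    Parameters
    ----------
    params : ModelParams
        Physical parameters; ``params.delay_steps`` sets the history length.
    discretization : {"euler", "exact"}
        Forward-Euler (default) or matrix-exponential (zero-order-hold)
        discretization of the base block.
    """
    Ac, B1c, B2c = _base_continuous(params)
    dt = params.time_step
    if discretization == "euler":
        Ad = np.eye(BASE_DIM) + dt * Ac
        B1d = dt * B1c
        B2d = dt * B2c
    elif discretization == "exact":
        Bc = np.hstack([B1c, B2c])
        Ad, Bd, *_ = cont2discrete((Ac, Bc, np.eye(BASE_DIM), 0), dt)
        B1d, B2d = Bd[:, :2], Bd[:, 2:]
    else:
        raise ValueError(f"unknown discretization {discretization!r}")

    n_delay = params.delay_steps
    n_aug = BASE_DIM * (n_delay + 1)
    A = np.zeros((n_aug, n_aug))
    A[:BASE_DIM, :BASE_DIM] = Ad
    for j in range(1, n_delay + 1):
        # history slot j receives an exact copy of slot j-1
        A[BASE_DIM * j:BASE_DIM * (j + 1),
          BASE_DIM * (j - 1):BASE_DIM * j] = np.eye(BASE_DIM)
    B1 = np.zeros((n_aug, 2))
    B2 = np.zeros((n_aug, 2))
    B1[:BASE_DIM] = B1d
    B2[:BASE_DIM] = B2d
    return DynamicsSpec(A=A, B1=B1, B2=B2, time_step=dt, delay_steps=n_delay)


def initial_state(params, geometry) -> np.ndarray:
    """Augmented initial state: hands at rest astride the midline.

    Hand 1 starts ``start_lateral_offset`` to the right of the midline and
    hand 2 the same distance to the left, so the center cursor starts on the
    midline; the target sits ``target_distance`` straight ahead.  All
    history slots are filled with the same base block (the system has been
    at rest).
    """
    base = np.zeros(BASE_DIM)
    base[IX_P1X] = +geometry.start_lateral_offset
    base[IX_P2X] = -geometry.start_lateral_offset
    base[IX_TY] = geometry.target_distance
    return np.tile(base, params.delay_steps + 1)


def base_block(x_aug: np.ndarray, slot: int = 0) -> np.ndarray:
    """Read history slot ``slot`` (0 = current) of an augmented state."""
    return x_aug[BASE_DIM * slot:BASE_DIM * (slot + 1)]
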