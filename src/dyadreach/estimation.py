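"""Delayed observations and Kalman state estimation.

Each player senses the world through a visual delay line: the observation
matrix reads the *oldest* history slot of the augmented state, i.e. the base
state ``n_delay`` steps in the past.  The observed channels are the player's
own hand position, velocity, and muscle force, the partner's hand position
and velocity (not the partner's force), and the center-cursor and target
positions — 14 channels in all.

State estimates combine an internal-model prediction with these delayed,
noisy measurements through a standard discrete-time Kalman filter whose
gains are precomputed by the forward covariance recursion.  The prediction
uses the player's own efference copy and a prediction of the partner's
command: under a partner representation, the partner's known gains applied
to the player's *own* estimate; without one, zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import BASE_DIM, DynamicsSpec
from .params import ModelParams

# channel offsets within a base block, per player perspective
_OWN = {1: dict(p=0, v=2, f=4), 2: dict(p=6, v=8, f=10)}
_PARTNER = {1: dict(p=6, v=8), 2: dict(p=0, v=2)}
_CC, _TARGET = 12, 14

N_CHANNELS = 14


@dataclass(frozen=True)
class ObservationSpec:
    """Observation matrix and measurement-noise covariance for one player."""

    C: np.ndarray               # (14, n_aug)
    noise_sd: np.ndarray        # (14,) per-channel measurement SDs
    delay_steps: int
    player: int

    @property
    def R_meas(self) -> np.ndarray:
        return np.diag(self.noise_sd ** 2)

    @property
    def cc_rows(self) -> np.ndarray:
        """Row indices reading the center-cursor position (x, y)."""
        return np.array([10, 11])

    @property
    def target_rows(self) -> np.ndarray:
        """Row indices reading the target position (x, y)."""
        return np.array([12, 13])


def build_observation(params: ModelParams, player: int = 1,
                      *, delay_steps: int | None = None) -> ObservationSpec:
    """Observation spec for one player.

    Channels (rows), each with x then y: own position, own velocity, own
    force, partner position, partner velocity, center-cursor position,
    target position.  All are read from the oldest delay slot; the
    partner's force is not observable.
    """
    if player not in (1, 2):
        raise ValueError("player must be 1 or 2")
    nd = params.delay_steps if delay_steps is None else delay_steps
    n_aug = BASE_DIM * (params.delay_steps + 1)
    slot = BASE_DIM * nd
    cols = []
    own, partner = _OWN[player], _PARTNER[player]
    for off in (own["p"], own["v"], own["f"], partner["p"], partner["v"],
                _CC, _TARGET):
        cols.extend([slot + off, slot + off + 1])
    C = np.zeros((N_CHANNELS, n_aug))
    C[np.arange(N_CHANNELS), cols] = 1.0
    sd = np.empty(N_CHANNELS)
    sd[[0, 1, 6, 7, 10, 11, 12, 13]] = params.noise_position
    sd[[2, 3, 8, 9]] = params.noise_velocity
    sd[[4, 5]] = params.noise_force
    return ObservationSpec(C=C, noise_sd=sd, delay_steps=nd, player=player)


def process_noise_cov(params: ModelParams, n_aug: int) -> np.ndarray:
    """Process-noise covariance: diagonal on the current base block only.

    History slots are deterministic copies, so they carry no process noise.
    """
    W = np.zeros((n_aug, n_aug))
    W[:BASE_DIM, :BASE_DIM] = params.process_noise ** 2 * np.eye(BASE_DIM)
    return W


def compute_kalman_gains(dyn: DynamicsSpec, obs: ObservationSpec,
                         process_noise: np.ndarray, horizon_steps: int,
                         *, P0: np.ndarray | None = None,
                         return_covariances: bool = False):
    """Time-indexed Kalman gains from the forward covariance recursion.

    Returns gains ``K`` of shape (horizon_steps, n_aug, n_channels), where
    ``K[k]`` applies to the innovation at step k+1 (the initial state is
    taken as known up to ``P0``, zero by default).  With
    ``return_covariances=True`` also returns the posterior covariance
    sequence.
    """
    A, C = dyn.A, obs.C
    V = obs.R_meas
    n = dyn.n_aug
    P = np.zeros((n, n)) if P0 is None else P0.copy()
    K = np.empty((horizon_steps, n, C.shape[0]))
    covs = np.empty((horizon_steps, n, n)) if return_covariances else None
    for k in range(horizon_steps):
        P = A @ P @ A.T + process_noise
        S = C @ P @ C.T + V
        try:
            Kk = np.linalg.solve(S, C @ P).T
        except np.linalg.LinAlgError as exc:
            raise RuntimeError(
                f"singular innovation covariance at step {k}: "
                f"cond(S) overflow; check measurement noise"
            ) from exc
        P = P - Kk @ C @ P
        P = 0.5 * (P + P.T)
        K[k] = Kk
        if covs is not None:
            covs[k] = P
    return (K, covs) if return_covariances else K


@dataclass
class Estimator:
    """Recursive Kalman estimator for one player.

    ``predict_partner`` controls the internal-model prediction of the
    partner's command: with a partner representation the player applies the
    partner's known gains to its own posterior estimate; without one it
    predicts zero.
    """

    dyn: DynamicsSpec           # internal model (may differ from the plant)
    obs: ObservationSpec
    K: np.ndarray               # (N, n_aug, n_channels)
    x_hat: np.ndarray           # posterior estimate

    def predict(self, u_self: np.ndarray, u_partner_pred: np.ndarray) -> np.ndarray:
        """Prior estimate from the internal model and efference copy."""
        if self.obs.player == 1:
            return (self.dyn.A @ self.x_hat + self.dyn.B1 @ u_self
                    + self.dyn.B2 @ u_partner_pred)
        return (self.dyn.A @ self.x_hat + self.dyn.B2 @ u_self
                + self.dyn.B1 @ u_partner_pred)

    def step(self, k: int, measurement: np.ndarray, u_self: np.ndarray,
             u_partner_pred: np.ndarray) -> np.ndarray:
        """One predict-update cycle; returns the new posterior estimate."""
        if measurement.shape != (self.obs.C.shape[0],):
            raise ValueError(
                f"measurement has shape {measurement.shape}, "
                f"expected ({self.obs.C.shape[0]},)"
            )
        prior = self.predict(u_self, u_partner_pred)
        innovation = measurement - self.obs.C @ prior
        self.x_hat = prior + self.K[k] @ innovation
        return self.x_hat
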