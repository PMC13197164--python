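"""Closed-loop simulation of reaching trials.

Three trial types are simulated for any condition x hypothesis:

* non-perturbation trials — a plain joint reach to the targets;
* perturbation trials — the displayed center cursor (or both targets)
  shifts 3 cm laterally once the center cursor has covered 25% of the
  forward distance, and stays shifted for the rest of the trial;
* probe trials — the same shift, but it ramps out over 25 ms, holds for
  200 ms, and ramps back over 25 ms, while both hands are held in a force
  channel that blocks lateral motion.  The lateral force each player pushes
  into the channel wall is the model's visuomotor feedback response.

The jump is purely visual: the physical state is untouched, and the
displacement enters each player's measurements through the delay line (a
measurement at step k reads the display as it was ``n_delay`` steps ago).
On probe trials the plant uses channel-modified input matrices (lateral
force column zeroed) while each player's internal model keeps the original
matrices — participants are unaware of the channel — and the reported
applied lateral force is the x-component of ``B1 u1`` under the original
input matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dynamics import (
    BASE_DIM,
    IDX_CC,
    IDX_P1,
    IDX_P2,
    IX_CCY,
    IX_F1X,
    IX_F2X,
    build_dynamics,
    initial_state,
)
from .estimation import (
    Estimator,
    build_observation,
    compute_kalman_gains,
    process_noise_cov,
)
from .gains import FeedbackGains, solve_gains
from .params import (
    CONDITIONS,
    Condition,
    DEFAULT_GEOMETRY,
    Geometry,
    Hypothesis,
    ModelParams,
    get_hypothesis,
)

TRIAL_TYPES = ("non_perturbation", "perturbation", "probe", "null_probe")
DIRECTION_SIGN = {"left": -1.0, "right": +1.0, "none": 0.0}


@dataclass(frozen=True)
class TrialSpec:
    """Fully resolved specification of one simulated trial."""

    condition: Condition
    trial_type: str
    jump_direction: str
    experiment: int                     # 1: cursor jump, 2: target jump
    geometry: Geometry = DEFAULT_GEOMETRY

    def __post_init__(self) -> None:
        if self.trial_type not in TRIAL_TYPES:
            raise ValueError(f"unknown trial_type {self.trial_type!r}")
        if self.experiment not in (1, 2):
            raise ValueError("experiment must be 1 or 2")
        if self.jump_direction not in DIRECTION_SIGN:
            raise ValueError(f"unknown direction {self.jump_direction!r}")
        has_jump = self.trial_type in ("perturbation", "probe")
        if has_jump and self.jump_direction == "none":
            raise ValueError(f"{self.trial_type} trials need a jump direction")
        if not has_jump and self.jump_direction != "none":
            raise ValueError(
                f"{self.trial_type} trials cannot have a jump direction"
            )

    @property
    def in_channel(self) -> bool:
        return self.trial_type in ("probe", "null_probe")

    def displacement(self, t_since_onset: float) -> float:
        """Lateral display offset (m) at time ``t`` after jump onset."""
        g = self.geometry
        sign = DIRECTION_SIGN[self.jump_direction]
        if sign == 0.0 or t_since_onset < 0:
            return 0.0
        ramp, mag = g.jump_ramp, g.jump_magnitude
        if self.trial_type == "perturbation":
            return sign * mag * min(t_since_onset / ramp, 1.0)
        # probe: ramp out, hold, ramp back
        hold_end = ramp + g.probe_hold
        if t_since_onset < ramp:
            return sign * mag * t_since_onset / ramp
        if t_since_onset < hold_end:
            return sign * mag
        if t_since_onset < hold_end + ramp:
            return sign * mag * (hold_end + ramp - t_since_onset) / ramp
        return 0.0


def make_trial_spec(condition, trial_type: str, direction: str = "none",
                    experiment: int = 1,
                    geometry: Geometry = DEFAULT_GEOMETRY) -> TrialSpec:
    """Validate labels and build a TrialSpec."""
    if not isinstance(condition, Condition):
        condition = Condition.from_label(str(condition))
    return TrialSpec(condition=condition, trial_type=trial_type,
                     jump_direction=direction, experiment=experiment,
                     geometry=geometry)


@dataclass
class TrialRecord:
    """Time series of one simulated trial (model time grid)."""

    time: np.ndarray                    # (N+1,) s from go cue
    hand1: np.ndarray                   # (N+1, 2) m
    hand2: np.ndarray                   # (N+1, 2) m
    center_cursor: np.ndarray           # (N+1, 2) m, as displayed
    applied_force1: np.ndarray          # (N,) N, lateral channel force
    applied_force2: np.ndarray
    spec: TrialSpec
    onset_step: int | None              # jump onset (None if no jump fired)
    seed: int | None

    @property
    def onset_time(self) -> float | None:
        return None if self.onset_step is None else self.time[self.onset_step]

    def to_frame(self, trial_id: int = 0) -> pd.DataFrame:
        """Tidy table: one row per sample."""
        n = len(self.time)
        f1 = np.append(self.applied_force1, np.nan)
        f2 = np.append(self.applied_force2, np.nan)
        return pd.DataFrame({
            "trial_id": trial_id,
            "t": self.time,
            "hand1_x": self.hand1[:, 0], "hand1_y": self.hand1[:, 1],
            "hand2_x": self.hand2[:, 0], "hand2_y": self.hand2[:, 1],
            "cc_x": self.center_cursor[:, 0], "cc_y": self.center_cursor[:, 1],
            "force1_x": f1, "force2_x": f2,
            "condition": self.spec.condition.label,
            "trial_type": self.spec.trial_type,
            "direction": self.spec.jump_direction,
            "experiment": self.spec.experiment,
        })


class SimulationError(RuntimeError):
    """Raised on numerical blow-up of the closed loop."""


_KALMAN_CACHE: dict = {}


def _kalman_gains_for(params: ModelParams):
    """Cached observation specs and Kalman gain sequences for both players."""
    if params not in _KALMAN_CACHE:
        dyn = build_dynamics(params)
        W = process_noise_cov(params, dyn.n_aug)
        out = []
        for player in (1, 2):
            obs = build_observation(params, player)
            K = compute_kalman_gains(dyn, obs, W, params.horizon_steps)
            out.append((obs, K))
        _KALMAN_CACHE[params] = tuple(out)
    return _KALMAN_CACHE[params]


def simulate_trial(gains: FeedbackGains, params: ModelParams, spec: TrialSpec,
                   seed: int | None = None, *, noise: bool = True,
                   state_norm_guard: float = 1e3) -> TrialRecord:
    """Closed-loop rollout of one trial.

    Both players run their Kalman estimators on delayed, noisy measurements
    and apply their feedback gains to their own posterior estimates.  With
    ``noise=False`` (or ``seed=None``) process and measurement noise are
    zeroed, giving a deterministic rollout.
    """
    dyn = build_dynamics(params)
    plant = dyn.channel_modified() if spec.in_channel else dyn
    N = params.horizon_steps
    if gains.horizon_steps != N:
        raise ValueError("gain sequence length does not match horizon_steps")
    nd = params.delay_steps
    dt = params.time_step
    g = spec.geometry
    rng = np.random.default_rng(seed) if (noise and seed is not None) else None

    (obs1, K1), (obs2, K2) = _kalman_gains_for(params)
    x = initial_state(params, g)
    # the internal model matches the plant: on channel trials neither
    # player's command can move anything laterally, in prediction or in fact
    est1 = Estimator(dyn=plant, obs=obs1, K=K1, x_hat=x.copy())
    est2 = Estimator(dyn=plant, obs=obs2, K=K2, x_hat=x.copy())

    hand1 = np.empty((N + 1, 2))
    hand2 = np.empty((N + 1, 2))
    cc = np.empty((N + 1, 2))
    af1 = np.empty(N)
    af2 = np.empty(N)
    offsets = np.zeros(N + 1)           # display offset at each absolute step
    onset_step: int | None = None

    def record(k: int) -> None:
        hand1[k] = x[IDX_P1]
        hand2[k] = x[IDX_P2]
        cc[k] = x[IDX_CC]
        if spec.experiment == 1:
            cc[k, 0] += offsets[k]      # displayed cursor includes the jump

    record(0)
    W_sd = params.process_noise
    for k in range(N):
        # jump onset: center cursor crosses 25% of the forward distance
        if (onset_step is None and spec.jump_direction != "none"
                and x[IX_CCY] >= g.onset_threshold):
            onset_step = k
        if onset_step is not None:
            offsets[k] = spec.displacement((k - onset_step) * dt)

        u1 = -gains.F1[k] @ est1.x_hat
        u2 = -gains.F2[k] @ est2.x_hat
        # applied lateral force: x-component of B1 u1 under the original B
        af1[k] = (dyn.B1 @ u1)[IX_F1X]
        af2[k] = (dyn.B2 @ u2)[IX_F2X]

        x = plant.A @ x + plant.B1 @ u1 + plant.B2 @ u2
        if rng is not None:
            w = W_sd * rng.standard_normal(BASE_DIM)
            if spec.in_channel:
                # rigid channel: no lateral dynamics at all
                w[[0, 2, 4, 6, 8, 10, 12]] = 0.0
            x[:BASE_DIM] += w
            # the displayed cursor is computed, not physical: it sits at the
            # hand midpoint exactly, noise or not
            x[IDX_CC] = 0.5 * (x[IDX_P1] + x[IDX_P2])
        if not np.all(np.isfinite(x)) or np.max(np.abs(x)) > state_norm_guard:
            raise SimulationError(f"state blow-up at step {k}")

        if onset_step is not None:
            offsets[k + 1] = spec.displacement((k + 1 - onset_step) * dt)
        record(k + 1)

        # measurements read the display as it was nd steps ago
        seen_offset = offsets[k + 1 - nd] if k + 1 - nd >= 0 else 0.0
        y1 = obs1.C @ x
        y2 = obs2.C @ x
        if seen_offset != 0.0:
            if spec.experiment == 1:
                y1[obs1.cc_rows[0]] += seen_offset
                y2[obs2.cc_rows[0]] += seen_offset
            else:
                y1[obs1.target_rows[0]] += seen_offset
                y2[obs2.target_rows[0]] += seen_offset
        if rng is not None:
            y1 = y1 + obs1.noise_sd * rng.standard_normal(obs1.noise_sd.size)
            y2 = y2 + obs2.noise_sd * rng.standard_normal(obs2.noise_sd.size)

        # internal-model prediction of the partner's command
        u2_pred = (-gains.F2[k] @ est1.x_hat if gains.partner_representation
                   else np.zeros(2))
        u1_pred = (-gains.F1[k] @ est2.x_hat if gains.partner_representation
                   else np.zeros(2))
        est1.step(k, y1, u1, u2_pred)
        est2.step(k, y2, u1_pred, u2)

    time = np.arange(N + 1) * dt
    return TrialRecord(time=time, hand1=hand1, hand2=hand2, center_cursor=cc,
                       applied_force1=af1, applied_force2=af2, spec=spec,
                       onset_step=onset_step, seed=seed)


def simulate_probe(gains: FeedbackGains, params: ModelParams, spec: TrialSpec,
                   seed: int | None = None, *, noise: bool = True) -> TrialRecord:
    """Simulate a force-channel probe trial (validates the trial type)."""
    if not spec.in_channel:
        raise ValueError("simulate_probe requires a probe or null_probe spec")
    return simulate_trial(gains, params, spec, seed, noise=noise)


# ---------------------------------------------------------------------------
# probe batches and model visuomotor feedback responses


@dataclass
class BatchResult:
    """Ensemble of probe-pair visuomotor feedback responses for a condition.

    ``vfr_traces`` holds one left-minus-right (experiment 1) or
    right-minus-left (experiment 2) applied-force difference trace per
    left/right probe pair, aligned so t=0 is the jump injection.
    """

    condition: Condition
    hypothesis: Hypothesis
    experiment: int
    time: np.ndarray                    # (T,) s from jump onset
    vfr_traces: np.ndarray              # (n_pairs, T)
    epoch_window: tuple[float, float] = (0.180, 0.230)

    @property
    def vfr_mean(self) -> np.ndarray:
        return self.vfr_traces.mean(axis=0)

    @property
    def vfr_sd(self) -> np.ndarray:
        return self.vfr_traces.std(axis=0, ddof=1) if len(self.vfr_traces) > 1 \
            else np.zeros_like(self.time)

    def epoch_means(self, window: tuple[float, float] | None = None) -> np.ndarray:
        """Per-pair mean VFR over a [start, end) window (default involuntary)."""
        lo, hi = window or self.epoch_window
        mask = (self.time >= lo - 1e-12) & (self.time < hi - 1e-12)
        return self.vfr_traces[:, mask].mean(axis=1)

    @property
    def involuntary_mean(self) -> float:
        return float(self.epoch_means().mean())


def _probe_force_from_onset(rec: TrialRecord, n_window: int) -> np.ndarray:
    if rec.onset_step is None:
        raise SimulationError("probe jump never fired (cursor did not cross "
                              "the onset threshold)")
    if rec.onset_step + n_window > len(rec.applied_force1):
        raise SimulationError("trial too short to cover the response window")
    return rec.applied_force1[rec.onset_step:rec.onset_step + n_window]


def run_batch(condition, hypothesis, params: ModelParams | None = None,
              n_trials: int = 100, seed: int | None = 0, *,
              experiment: int = 1, noise: bool = True,
              window: float = 0.45,
              geometry: Geometry = DEFAULT_GEOMETRY) -> BatchResult:
    """Simulate a batch of probe trials and form model VFR traces.

    ``n_trials`` counts probe trials in total, split evenly between left
    and right jumps; the i-th left and i-th right probes are differenced
    (per the experiment's sign convention) to give one VFR trace per pair.
    Player 1's applied force is analyzed; by symmetry player 2 realizes the
    swapped condition.  Deterministic given ``seed``.
    """
    params = params or ModelParams()
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if not isinstance(condition, Condition):
        condition = Condition.from_label(str(condition))
    if isinstance(hypothesis, str):
        hypothesis = get_hypothesis(hypothesis)
    dyn = build_dynamics(params)
    gains = solve_gains(dyn, condition, hypothesis, params)
    n_pairs = max(n_trials // 2, 1)
    n_window = int(round(window / params.time_step)) + 1
    ss = np.random.SeedSequence(seed if seed is not None else 0)
    child = ss.generate_state(2 * n_pairs, dtype=np.uint32) if noise else None

    traces = np.empty((n_pairs, n_window))
    for i in range(n_pairs):
        recs = {}
        for j, direction in enumerate(("left", "right")):
            spec = make_trial_spec(condition, "probe", direction, experiment,
                                   geometry)
            s = int(child[2 * i + j]) if noise else None
            recs[direction] = simulate_trial(gains, params, spec, s, noise=noise)
        left = _probe_force_from_onset(recs["left"], n_window)
        right = _probe_force_from_onset(recs["right"], n_window)
        traces[i] = (left - right) if experiment == 1 else (right - left)
        if not noise:
            traces = np.repeat(traces[:1], n_pairs, axis=0)
            break
    time = np.arange(n_window) * params.time_step
    return BatchResult(condition=condition, hypothesis=hypothesis,
                       experiment=experiment, time=time, vfr_traces=traces)


def model_predictions(hypothesis, params: ModelParams | None = None, *,
                      experiment: int = 1, n_trials: int = 100,
                      seed: int | None = None,
                      noise: bool = False) -> dict[str, float]:
    """Involuntary-epoch model VFR per condition (noise-free by default)."""
    out = {}
    for cond in CONDITIONS:
        batch = run_batch(cond, hypothesis, params, n_trials=n_trials,
                          seed=seed, experiment=experiment, noise=noise)
        out[cond.label] = batch.involuntary_mean
    return out
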