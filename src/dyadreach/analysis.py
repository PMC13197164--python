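"""Visuomotor feedback response (VFR) analysis of probe-trial force traces.

The pipeline mirrors standard force-channel analyses: traces are low-pass
filtered (5th-order Butterworth, 14 Hz cutoff, zero-phase), re-timed so t=0
is the instant the jump was actually displayed (display latency 42 ms for
recorded data), and differenced between left and right jump probes.  The
resulting response trace is summarized by its mean over three epochs after
visual presentation: involuntary 180-230 ms, semi-involuntary 230-300 ms,
and voluntary 300-400 ms (half-open windows on the sample grid).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt

#: Epoch windows (s), half-open [start, end).
EPOCHS = {
    "involuntary": (0.180, 0.230),
    "semi_involuntary": (0.230, 0.300),
    "voluntary": (0.300, 0.400),
}

DISPLAY_DELAY = 0.042  # s, LCD presentation latency for recorded data


@dataclass(frozen=True)
class ResponseTrace:
    """A force-difference trace on a time axis anchored at presentation."""

    time: np.ndarray        # s, 0 = visual presentation of the jump
    force: np.ndarray       # N
    experiment: int = 1
    participant: str | int | None = None
    condition: str | None = None

    def __post_init__(self) -> None:
        if self.time.shape != self.force.shape:
            raise ValueError("time and force must have equal length")


@dataclass(frozen=True)
class EpochSummary:
    """Mean response per epoch (N)."""

    involuntary: float
    semi_involuntary: float
    voluntary: float

    def as_dict(self) -> dict[str, float]:
        return {"involuntary": self.involuntary,
                "semi_involuntary": self.semi_involuntary,
                "voluntary": self.voluntary}


def lowpass(trace: np.ndarray, sample_rate: float, *, order: int = 5,
            cutoff: float = 14.0) -> np.ndarray:
    """Zero-phase Butterworth low-pass filter (forward-backward pass).

    The dual pass squares the magnitude response, so the effective
    attenuation is doubled relative to a single pass; DC gain stays 1.
    """
    trace = np.asarray(trace, dtype=float)
    if sample_rate <= 2 * cutoff:
        raise ValueError("sample_rate must exceed twice the cutoff")
    b, a = butter(order, cutoff, fs=sample_rate)
    padlen = 3 * (max(len(a), len(b)) - 1)
    if trace.shape[-1] <= padlen:
        raise ValueError(
            f"trace too short for filter warm-up ({trace.shape[-1]} <= {padlen})"
        )
    return filtfilt(b, a, trace, axis=-1)


def align_trace(time: np.ndarray, jump_command_time: float,
                display_delay: float = DISPLAY_DELAY) -> np.ndarray:
    """Re-time an axis so 0 falls at command time plus display latency."""
    time = np.asarray(time, dtype=float)
    presentation = jump_command_time + display_delay
    if not (time[0] <= presentation <= time[-1]):
        raise ValueError(
            f"alignment point {presentation} s outside trace span "
            f"[{time[0]}, {time[-1]}]"
        )
    return time - presentation


def visuomotor_response(left_forces: np.ndarray, right_forces: np.ndarray,
                        experiment: int = 1) -> np.ndarray:
    """Left/right probe force difference per the experiment's convention.

    Experiment 1 (cursor jumps): mean(left) - mean(right).
    Experiment 2 (target jumps): mean(right) - mean(left).
    Inputs are (n_trials, T) stacks or single (T,) traces, already aligned.
    """
    left = np.atleast_2d(np.asarray(left_forces, dtype=float))
    right = np.atleast_2d(np.asarray(right_forces, dtype=float))
    if left.shape[-1] != right.shape[-1]:
        raise ValueError("left and right traces must have equal length")
    diff = left.mean(axis=0) - right.mean(axis=0)
    if experiment == 1:
        return diff
    if experiment == 2:
        return -diff
    raise ValueError("experiment must be 1 or 2")


def epoch_means(trace: ResponseTrace | None = None, *,
                time: np.ndarray | None = None,
                force: np.ndarray | None = None) -> EpochSummary:
    """Mean response over the three epochs (half-open windows)."""
    if trace is not None:
        time, force = trace.time, trace.force
    time = np.asarray(time, dtype=float)
    force = np.asarray(force, dtype=float)
    if time[0] > EPOCHS["involuntary"][0] or time[-1] < EPOCHS["voluntary"][1] - 1e-9:
        raise ValueError("trace must cover 0-400 ms after presentation")
    out = {}
    for name, (lo, hi) in EPOCHS.items():
        mask = (time >= lo - 1e-12) & (time < hi - 1e-12)
        if not mask.any():
            raise ValueError(f"no samples fall in the {name} window")
        out[name] = float(force[mask].mean())
    return EpochSummary(**out)


def final_lateral_deviation(non_perturbation_finals: np.ndarray,
                            perturbation_finals: np.ndarray,
                            perturbation_directions=None) -> float:
    """Voluntary correction metric from final lateral hand positions (m).

    Difference between the average final lateral hand position on
    non-perturbation trials and on perturbation trials.  Left-jump trials
    are mirrored about the non-perturbation mean before averaging
    (sign-folding), so corrections in either direction accumulate with the
    same sign.
    """
    np_fin = np.asarray(non_perturbation_finals, dtype=float)
    p_fin = np.asarray(perturbation_finals, dtype=float)
    if np_fin.size == 0 or p_fin.size == 0:
        raise ValueError("both trial sets must be non-empty")
    baseline = np_fin.mean()
    folded = p_fin.copy()
    if perturbation_directions is not None:
        directions = np.asarray(perturbation_directions)
        if directions.shape != p_fin.shape:
            raise ValueError("directions must match perturbation trials")
        # mirror left-jump trials about the baseline
        left = directions == "left"
        folded[left] = 2 * baseline - folded[left]
    return float(baseline - folded.mean())
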