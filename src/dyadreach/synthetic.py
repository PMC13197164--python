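"""Synthetic datasets with the structure the analysis pipeline assumes.

A generated dataset mimics one experiment: 24 pairs, four blocked
conditions per pair, and per block a lead-in non-perturbation trial plus 10
randomly interleaved sets of 15 trials (8 non-perturbation, 2 left + 2
right perturbation, 1 left + 1 right + 1 null probe), i.e. 81/40/30 trials
per block.  In a block, one participant's target widths give them condition
"self X / partner Y" while their partner simultaneously realizes the
swapped condition, so four blocks give every participant all four
conditions.

Probe trials carry 1000 Hz lateral force traces: a smooth onset rising to a
plateau whose involuntary-epoch (180-230 ms) mean equals the participant's
condition mean.  Condition means come from an *effect model* — by default
the game model's own noise-free probe predictions for a chosen hypothesis —
plus between-participant Gaussian variability; white trial noise is added
on top.  The plateau amplitude is pre-divided by the analysis filter's gain
on the unit shape, so with all noise at zero the analysis pipeline returns
the injected involuntary epoch means exactly (a closed pipeline identity).

Perturbation and non-perturbation trials carry only final lateral hand
positions (all the deviation metric consumes), built from a simple
condition-dependent correction rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

from .analysis import DISPLAY_DELAY, EPOCHS, lowpass
from .params import CONDITION_LABELS, CONDITIONS, Condition, ModelParams

SAMPLE_RATE = 1000.0  # Hz, recorded-data rate emulated on probe trials

#: trial composition of one interleaved set
SET_COMPOSITION = (
    ["non_perturbation"] * 8
    + [("perturbation", "left")] * 2 + [("perturbation", "right")] * 2
    + [("probe", "left"), ("probe", "right"), ("null_probe", "none")]
)
SETS_PER_BLOCK = 10


# ---------------------------------------------------------------------------
# effect model


@lru_cache(maxsize=8)
def _model_effects(hypothesis_label: str, experiment: int,
                   params: ModelParams) -> tuple[float, ...]:
    from .simulate import model_predictions
    preds = model_predictions(hypothesis_label, params, experiment=experiment,
                              noise=False)
    return tuple(preds[c] for c in CONDITION_LABELS)


def effect_model(hypothesis, condition=None, *, experiment: int = 1,
                 params: ModelParams | None = None,
                 scale: float = 1.0) -> float | dict[str, float]:
    """Expected involuntary-epoch mean (N) per condition.

    Values are the game model's noise-free probe-batch predictions for the
    hypothesis (computed once and cached), optionally scaled.  With
    ``condition=None`` returns the full label -> value dict.
    """
    label = hypothesis if isinstance(hypothesis, str) else hypothesis.label
    params = params or ModelParams()
    vals = _model_effects(label, experiment, params)
    table = {c: scale * v for c, v in zip(CONDITION_LABELS, vals)}
    if condition is None:
        return table
    key = condition.label if isinstance(condition, Condition) else str(condition)
    if key not in table:
        raise ValueError(f"unknown condition {key!r}")
    return table[key]


def null_effects(value: float = 0.3) -> dict[str, float]:
    """An effect model with all condition means equal (for null studies)."""
    return {c: value for c in CONDITION_LABELS}


# ---------------------------------------------------------------------------
# probe force-trace shape

_T_PRE = 0.100      # s of trace before the jump command
_T_POST = 0.550     # s after it
_RISE_START = 0.100  # s after presentation
_RISE_END = 0.170    # settled well before the involuntary window opens


def probe_time_axis() -> np.ndarray:
    """Time axis (s) of synthetic probe traces, 0 = jump command."""
    n = int(round((_T_PRE + _T_POST) * SAMPLE_RATE)) + 1
    return np.arange(n) / SAMPLE_RATE - _T_PRE


def unit_shape(time_from_command: np.ndarray) -> np.ndarray:
    """Smoothstep onset to a unit plateau, keyed to the presentation time."""
    s = (time_from_command - DISPLAY_DELAY - _RISE_START) / (_RISE_END - _RISE_START)
    s = np.clip(s, 0.0, 1.0)
    return s * s * s * (s * (6.0 * s - 15.0) + 10.0)  # quintic smoothstep


@lru_cache(maxsize=1)
def _involuntary_gain() -> float:
    """Analysis-filter gain of the unit shape over the involuntary window."""
    t = probe_time_axis()
    filt = lowpass(unit_shape(t), SAMPLE_RATE)
    rel = t - DISPLAY_DELAY
    lo, hi = EPOCHS["involuntary"]
    mask = (rel >= lo - 1e-12) & (rel < hi - 1e-12)
    return float(filt[mask].mean())


# ---------------------------------------------------------------------------
# dataset containers


@dataclass
class ProbeSet:
    """One participant's probe-trial force traces for one condition."""

    time: np.ndarray            # s, 0 = jump command
    forces: np.ndarray          # (n_trials, T) N
    directions: np.ndarray      # (n_trials,) 'left' | 'right' | 'none'


@dataclass
class PairDataset:
    """A full synthetic experiment.

    ``trials`` lists the per-pair trial sequences; ``probe_sets`` maps
    (participant, condition label) to that participant's probe traces;
    ``finals`` holds final lateral hand positions for non-perturbation and
    perturbation trials; ``truth`` records the injected per-participant
    involuntary epoch means.
    """

    experiment: int
    seed: int
    hypothesis: str
    trials: pd.DataFrame
    probe_sets: dict[tuple[str, str], ProbeSet]
    finals: pd.DataFrame
    truth: pd.DataFrame
    manifest: dict = field(default_factory=dict)

    @property
    def participants(self) -> list[str]:
        return sorted(self.truth["participant"].unique())


# simple condition-dependent voluntary-correction rule (m) for final
# lateral hand positions on perturbation trials
def _correction(self_relevant: bool, partner_relevant: bool,
                jump: float = 0.03) -> float:
    if self_relevant and partner_relevant:
        return jump
    if self_relevant:
        return 1.5 * jump       # carries most of the correction alone
    if partner_relevant:
        return 0.5 * jump       # helps the partner part-way
    return 0.05 * jump


def generate_dataset(hypothesis: str = "rep_weighted", *, n_pairs: int = 24,
                     seed: int = 0, experiment: int = 1,
                     effects: dict[str, float] | None = None,
                     effect_scale: float = 1.0,
                     between_sd: float = 0.2,
                     trial_sd: float = 0.3,
                     final_pos_sd: float = 0.005,
                     n_sets: int = SETS_PER_BLOCK,
                     params: ModelParams | None = None) -> PairDataset:
    """Generate a synthetic experiment dataset.

    Parameters mirror the study conditions: 24 pairs, 10 sets per block.
    ``effects`` overrides the model-derived condition means (N);
    ``between_sd`` is the between-participant SD of the involuntary epoch
    mean (N) and ``trial_sd`` the white within-trial force noise SD (N).
    Fixed seed gives an identical dataset.
    """
    if n_pairs < 1 or n_sets < 1:
        raise ValueError("n_pairs and n_sets must be >= 1")
    if effects is None:
        effects = effect_model(hypothesis, experiment=experiment,
                               params=params, scale=effect_scale)
    rng = np.random.default_rng(seed)
    time = probe_time_axis()
    shape = unit_shape(time)
    gain = _involuntary_gain()
    # probe sign convention: the differenced response must recover mu
    pos_dir = "left" if experiment == 1 else "right"

    trial_rows = []
    probe_sets: dict[tuple[str, str], ProbeSet] = {}
    final_rows = []
    truth_rows = []

    block_designs = [(a, b) for a in (False, True) for b in (False, True)]
    for ip in range(n_pairs):
        pair = f"P{ip + 1:02d}"
        members = {f"{pair}A": 1, f"{pair}B": 2}
        for a_rel, b_rel in block_designs:
            cond = {f"{pair}A": Condition(self_relevant=a_rel, partner_relevant=b_rel),
                    f"{pair}B": Condition(self_relevant=b_rel, partner_relevant=a_rel)}
            # shared trial sequence for the pair
            sequence = [("non_perturbation", "none")]  # lead-in
            for _ in range(n_sets):
                chunk = [(t, "none") if isinstance(t, str) else t
                         for t in SET_COMPOSITION]
                rng.shuffle(chunk)
                sequence.extend(chunk)
            for idx, (ttype, direction) in enumerate(sequence):
                trial_rows.append((pair, f"{a_rel:d}{b_rel:d}", idx, ttype,
                                   direction))
            # per-participant signals
            for pid, c in cond.items():
                mu = effects[c.label] + rng.normal(0.0, between_sd)
                truth_rows.append((pid, c.label, mu))
                amp = mu / (2.0 * gain)
                probes = [(i, d) for i, (t, d) in enumerate(sequence)
                          if t in ("probe", "null_probe")]
                forces = np.empty((len(probes), time.size))
                dirs = []
                for j, (i, d) in enumerate(probes):
                    if d == "none":
                        base = np.zeros_like(time)
                    else:
                        sign = 1.0 if d == pos_dir else -1.0
                        base = sign * amp * shape
                    forces[j] = base + rng.normal(0.0, trial_sd, time.size)
                    dirs.append(d)
                probe_sets[(pid, c.label)] = ProbeSet(
                    time=time, forces=forces, directions=np.array(dirs))
                corr = _correction(c.self_relevant, c.partner_relevant)
                for i, (ttype, d) in enumerate(sequence):
                    if ttype == "probe" or ttype == "null_probe":
                        continue
                    base_x = 0.13 + rng.normal(0.0, final_pos_sd)
                    if ttype == "perturbation":
                        # hands shift opposite the displayed jump
                        shift = corr * (1.0 if d == "left" else -1.0)
                        base_x += shift + rng.normal(0.0, 0.2 * corr + 1e-6)
                    final_rows.append((pid, c.label, ttype, d, base_x))

    trials = pd.DataFrame(trial_rows, columns=["pair", "block", "trial_index",
                                               "trial_type", "direction"])
    finals = pd.DataFrame(final_rows, columns=["participant", "condition",
                                               "trial_type", "direction",
                                               "final_x"])
    truth = pd.DataFrame(truth_rows, columns=["participant", "condition", "mu"])
    manifest = dict(hypothesis=hypothesis, n_pairs=n_pairs, seed=seed,
                    experiment=experiment, effects=dict(effects),
                    effect_scale=effect_scale, between_sd=between_sd,
                    trial_sd=trial_sd, n_sets=n_sets)
    return PairDataset(experiment=experiment, seed=seed, hypothesis=hypothesis,
                       trials=trials, probe_sets=probe_sets, finals=finals,
                       truth=truth, manifest=manifest)


#: epoch-mean residual SD from trial noise after filtering and averaging,
#: matched to the trace path defaults (trial_sd=0.3, 10 probes/direction)
_RESIDUAL_SD = 0.012


def generate_epoch_table(hypothesis: str = "rep_weighted", *,
                         n_participants: int = 48, seed: int = 0,
                         experiment: int = 1,
                         effects: dict[str, float] | None = None,
                         effect_scale: float = 1.0,
                         between_sd: float = 0.2,
                         residual_sd: float = _RESIDUAL_SD,
                         params: ModelParams | None = None) -> pd.DataFrame:
    """Fast path: draw the involuntary epoch table directly.

    Statistically equivalent to generating the full dataset and running the
    analysis pipeline: participant x condition means are the effect model
    plus between-participant noise, plus the small residual the filtered,
    trial-averaged trace noise would leave.  Used for power studies.
    """
    if effects is None:
        effects = effect_model(hypothesis, experiment=experiment,
                               params=params, scale=effect_scale)
    rng = np.random.default_rng(seed)
    data = {}
    for c in CONDITION_LABELS:
        data[c] = (effects[c]
                   + rng.normal(0.0, between_sd, n_participants)
                   + rng.normal(0.0, residual_sd, n_participants))
    table = pd.DataFrame(data)
    table.index = [f"S{i + 1:02d}" for i in range(n_participants)]
    return table
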