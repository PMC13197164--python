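"""Model parameters, experimental conditions, and control-policy hypotheses.

The model describes two players (controllers) who each move a point-mass
"hand" in the horizontal plane and jointly steer a *center cursor* located at
the midpoint of the two hands toward laterally aligned targets.  Each player's
target is either narrow (task-relevant: lateral error matters) or wide
(task-irrelevant: lateral error is free), giving a 2 x 2 condition design.

Four hypotheses about the control policy are distinguished by (i) whether a
player's feedback gains are computed with knowledge of the partner's policy
(partner representation) and (ii) how strongly the partner's cost enters the
player's own objective (the joint-cost weight ``alpha``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum


class Relevance(str, Enum):
    """Target relevance: narrow targets demand lateral correction."""

    RELEVANT = "relevant"
    IRRELEVANT = "irrelevant"


@dataclass(frozen=True)
class Condition:
    """A 2 x 2 target-relevance condition, seen from player 1 ("self")."""

    self_relevant: bool
    partner_relevant: bool

    @property
    def label(self) -> str:
        p = "pr" if self.partner_relevant else "pi"
        s = "sr" if self.self_relevant else "si"
        return f"{p}/{s}"

    @classmethod
    def from_label(cls, label: str) -> "Condition":
        try:
            p, s = label.strip().lower().split("/")
            return cls(self_relevant={"sr": True, "si": False}[s],
                       partner_relevant={"pr": True, "pi": False}[p])
        except (ValueError, KeyError):
            raise ValueError(
                f"unknown condition label {label!r}; expected e.g. 'pr/si'"
            ) from None

    def swapped(self) -> "Condition":
        """The same block seen from the partner's perspective."""
        return Condition(self_relevant=self.partner_relevant,
                         partner_relevant=self.self_relevant)


#: The four conditions in canonical order.
CONDITIONS = (
    Condition(False, False),  # pi/si
    Condition(False, True),   # pr/si
    Condition(True, False),   # pi/sr
    Condition(True, True),    # pr/sr
)

CONDITION_LABELS = tuple(c.label for c in CONDITIONS)


@dataclass(frozen=True)
class Hypothesis:
    """A control-policy hypothesis.

    Attributes
    ----------
    label
        One of ``no_rep_self``, ``rep_self``, ``rep_equal``, ``rep_weighted``.
    partner_representation
        If True, gains are the Nash equilibrium of the coupled game; if
        False, each player solves a single-player problem assuming the
        partner never acts (``F2 = 0``), and the estimator predicts a zero
        partner command.
    alpha
        Weight on the partner's individual cost inside the player's joint
        cost, ``J_i + alpha * J_j``.
    """

    label: str
    partner_representation: bool
    alpha: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")


#: Fixed mapping of hypothesis labels to policy structure.
HYPOTHESES: dict[str, Hypothesis] = {
    "no_rep_self": Hypothesis("no_rep_self", partner_representation=False, alpha=0.0),
    "rep_self": Hypothesis("rep_self", partner_representation=True, alpha=0.0),
    "rep_equal": Hypothesis("rep_equal", partner_representation=True, alpha=1.0),
    "rep_weighted": Hypothesis("rep_weighted", partner_representation=True, alpha=0.5),
}


def get_hypothesis(label: str) -> Hypothesis:
    try:
        return HYPOTHESES[label]
    except KeyError:
        raise ValueError(
            f"unknown hypothesis {label!r}; expected one of {sorted(HYPOTHESES)}"
        ) from None


@dataclass(frozen=True)
class ModelParams:
    """Physical, cost, and noise parameters of the two-player game.

    Units are SI throughout (m, s, N, kg).  The defaults reproduce the
    study conditions: 1.5 kg point-mass hands with light viscosity, a 20 ms
    first-order muscle filter, 110 ms visual feedback delay on a 10 ms
    simulation grid, and terminal center-cursor weights of 40,000 (relevant
    target) versus 100 (irrelevant target).
    """

    hand_mass: float = 1.5                  # kg
    viscosity: float = 0.1                  # N s / m
    muscle_time_constant: float = 0.020     # s
    time_step: float = 0.010                # s
    sensory_delay: float = 0.110            # s
    horizon_steps: int = 130                # 1.3 s: ~0.8 s reach + stabilization
    terminal_weight_relevant: float = 40_000.0
    terminal_weight_irrelevant: float = 100.0
    terminal_weight_forward: float = 40_000.0   # forward accuracy always matters
    terminal_weight_velocity: float = 10.0      # own-hand terminal velocity
    terminal_weight_force: float = 0.01         # own-hand terminal muscle force
    control_weight: float = 0.1                 # R = r * I per step
    # measurement noise SDs per channel class
    noise_position: float = 0.002           # m
    noise_velocity: float = 0.02            # m / s
    noise_force: float = 0.02               # N
    process_noise: float = 1e-3             # SD on every base-state row

    def __post_init__(self) -> None:
        for name in ("hand_mass", "viscosity", "muscle_time_constant",
                     "time_step", "sensory_delay"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.horizon_steps < 1:
            raise ValueError("horizon_steps must be >= 1")
        ratio = self.sensory_delay / self.time_step
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError(
                "sensory_delay must be an integer multiple of time_step "
                f"(got {self.sensory_delay} / {self.time_step})"
            )

    @property
    def delay_steps(self) -> int:
        """Number of time steps in the sensory delay line."""
        return round(self.sensory_delay / self.time_step)

    def with_(self, **overrides) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **overrides)


@dataclass(frozen=True)
class Geometry:
    """Workspace geometry of the reaching task (m)."""

    target_distance: float = 0.25       # forward reach extent
    start_lateral_offset: float = 0.13  # each hand starts this far from midline
    narrow_width: float = 0.0105
    wide_width: float = 0.20
    target_height: float = 0.0125
    jump_magnitude: float = 0.03        # lateral cursor/target jump
    jump_ramp: float = 0.025            # s, linear shift duration
    probe_hold: float = 0.200           # s, displaced plateau on probe trials

    @property
    def onset_threshold(self) -> float:
        """Forward distance at which jumps trigger (25% of the reach)."""
        return 0.25 * self.target_distance


DEFAULT_GEOMETRY = Geometry()
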