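"""Tabular readers/writers, run configuration, and manifests.

All interchange is plain comma-separated text with a header row.  Probe
force traces travel in a long (tidy) layout, one row per sample; because
deposited datasets name their columns differently, the reader takes an
explicit column mapping and optional unit scale factors.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .params import CONDITION_LABELS, ModelParams
from .synthetic import PairDataset, ProbeSet

#: canonical field -> meaning; values of the user mapping are column names
REQUIRED_FIELDS = ("participant", "condition", "trial", "direction", "time",
                   "force")

DEFAULT_MAPPING = {f: f for f in REQUIRED_FIELDS}


class SchemaError(ValueError):
    """A required column is missing or a row cannot be parsed."""


def write_probe_table(dataset: PairDataset, path) -> Path:
    """Write all probe-trial force traces as one tidy table."""
    frames = []
    for (pid, cond), ps in dataset.probe_sets.items():
        n, t = ps.forces.shape
        frames.append(pd.DataFrame({
            "participant": np.repeat(pid, n * t),
            "condition": cond,
            "trial": np.repeat(np.arange(n), t),
            "direction": np.repeat(ps.directions, t),
            "time": np.tile(ps.time, n),
            "force": ps.forces.ravel(),
        }))
    path = Path(path)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    return path


def load_trial_table(path, column_mapping: dict | None = None, *,
                     units: dict | None = None, experiment: int = 1,
                     seed: int = -1) -> PairDataset:
    """Read a tidy probe-force table into a PairDataset.

    ``column_mapping`` maps the canonical fields (participant, condition,
    trial, direction, time, force) to the file's column names;
    ``units`` gives per-field multiplicative factors into SI (s, N), e.g.
    ``{"time": 1e-3}`` for milliseconds.
    """
    mapping = dict(DEFAULT_MAPPING)
    if column_mapping:
        mapping.update(column_mapping)
    missing_fields = [f for f in REQUIRED_FIELDS if f not in mapping]
    if missing_fields:
        raise SchemaError(f"column mapping omits required fields {missing_fields}")
    path = Path(path)
    df = pd.read_csv(path)
    missing = [col for col in mapping.values() if col not in df.columns]
    if missing:
        raise SchemaError(f"{path.name} is missing required columns {missing}")
    df = df.rename(columns={v: k for k, v in mapping.items()})
    for fld in ("time", "force"):
        vals = pd.to_numeric(df[fld], errors="coerce")
        bad = vals.isna() & df[fld].notna()
        if bad.any():
            raise SchemaError(
                f"malformed {fld} value at row {int(np.flatnonzero(bad)[0])}"
            )
        factor = (units or {}).get(fld, 1.0)
        df[fld] = vals * factor

    probe_sets: dict[tuple[str, str], ProbeSet] = {}
    for (pid, cond), g in df.groupby(["participant", "condition"], sort=True):
        trials = []
        dirs = []
        time = None
        for trial, tg in g.groupby("trial", sort=True):
            tg = tg.sort_values("time")
            if time is None:
                time = tg["time"].to_numpy()
            elif len(tg) != len(time):
                raise SchemaError(
                    f"trial {trial} of {pid}/{cond} has {len(tg)} samples, "
                    f"expected {len(time)}"
                )
            trials.append(tg["force"].to_numpy())
            dirs.append(str(tg["direction"].iloc[0]))
        probe_sets[(str(pid), str(cond))] = ProbeSet(
            time=time, forces=np.vstack(trials), directions=np.array(dirs))
    truth = pd.DataFrame({"participant": [p for p, c in probe_sets],
                          "condition": [c for p, c in probe_sets],
                          "mu": np.nan})
    return PairDataset(experiment=experiment, seed=seed, hypothesis="recorded",
                       trials=pd.DataFrame(), probe_sets=probe_sets,
                       finals=pd.DataFrame(columns=["participant", "condition",
                                                    "trial_type", "direction",
                                                    "final_x"]),
                       truth=truth,
                       manifest={"source": str(path)})


def write_epoch_table(table: pd.DataFrame, path) -> Path:
    path = Path(path)
    table.rename_axis("participant").to_csv(path)
    return path


def read_epoch_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col="participant")
    missing = [c for c in CONDITION_LABELS if c not in df.columns]
    if missing:
        raise SchemaError(f"epoch table missing condition columns {missing}")
    return df[list(CONDITION_LABELS)]


def export_gains(gains, path) -> Path:
    """Write gain sequences as a tidy table (step, player, row, col, value)."""
    frames = []
    for player, F in ((1, gains.F1), (2, gains.F2)):
        steps, m, n = F.shape
        idx = np.indices((steps, m, n)).reshape(3, -1)
        frames.append(pd.DataFrame({"step": idx[0], "player": player,
                                    "row": idx[1], "col": idx[2],
                                    "value": F.ravel()}))
    path = Path(path)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    return path


@dataclass
class RunConfig:
    """Configuration of a reproducible pipeline run."""

    experiment: int = 1
    hypothesis: str = "rep_weighted"
    conditions: tuple = CONDITION_LABELS
    n_trials: int = 100
    n_pairs: int = 24
    n_boot: int = 1_000_000
    seed: int = 0
    model: dict = field(default_factory=dict)   # ModelParams overrides
    output_dir: str = "."

    def model_params(self) -> ModelParams:
        return ModelParams(**self.model)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        if "conditions" in raw:
            raw["conditions"] = tuple(raw["conditions"])
        return cls(**raw)

    def write_manifest(self, path, **extra) -> Path:
        from importlib.metadata import version
        try:
            ver = version("dyadreach")
        except Exception:
            ver = "unknown"
        payload = {"config": {**asdict(self),
                              "conditions": list(self.conditions)},
                   "software_version": ver, **extra}
        path = Path(path)
        path.write_text(json.dumps(payload, indent=2, default=str) + "\n")
        return path
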