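"""Glue between datasets and the analysis/statistics stages.

Turns a :class:`~dyadreach.synthetic.PairDataset` (or a dataset loaded from
tables) into per-participant response traces, epoch tables, final-deviation
tables, and a statistics report.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .analysis import (
    DISPLAY_DELAY,
    EPOCHS,
    ResponseTrace,
    align_trace,
    epoch_means,
    final_lateral_deviation,
    lowpass,
    visuomotor_response,
)
from .params import CONDITION_LABELS
from .stats import analyze_epoch_table
from .synthetic import SAMPLE_RATE, PairDataset


def participant_response(dataset: PairDataset, participant: str,
                         condition: str) -> ResponseTrace:
    """Aligned, filtered, left/right-differenced response for one cell."""
    try:
        ps = dataset.probe_sets[(participant, condition)]
    except KeyError:
        raise KeyError(f"no probe data for {participant!r} in {condition!r}") \
            from None
    time = align_trace(ps.time, jump_command_time=0.0,
                       display_delay=DISPLAY_DELAY)
    filtered = lowpass(ps.forces, SAMPLE_RATE)
    left = filtered[ps.directions == "left"]
    right = filtered[ps.directions == "right"]
    force = visuomotor_response(left, right, dataset.experiment)
    return ResponseTrace(time=time, force=force, experiment=dataset.experiment,
                         participant=participant, condition=condition)


def epoch_tables(dataset: PairDataset) -> dict[str, pd.DataFrame]:
    """Per-epoch tables of mean responses, participants x conditions."""
    rows: dict[str, dict[str, dict[str, float]]] = {e: {} for e in EPOCHS}
    for pid in dataset.participants:
        for cond in CONDITION_LABELS:
            summary = epoch_means(participant_response(dataset, pid, cond))
            for epoch, value in summary.as_dict().items():
                rows[epoch].setdefault(pid, {})[cond] = value
    return {epoch: pd.DataFrame.from_dict(d, orient="index")[list(CONDITION_LABELS)]
            for epoch, d in rows.items()}


def final_deviation_table(dataset: PairDataset) -> pd.DataFrame:
    """Final lateral hand deviation (m) per participant x condition."""
    out: dict[str, dict[str, float]] = {}
    g = dataset.finals.groupby(["participant", "condition", "trial_type"])
    for pid in dataset.participants:
        for cond in CONDITION_LABELS:
            non = g.get_group((pid, cond, "non_perturbation"))
            pert = g.get_group((pid, cond, "perturbation"))
            dev = final_lateral_deviation(
                non["final_x"].to_numpy(), pert["final_x"].to_numpy(),
                pert["direction"].to_numpy())
            out.setdefault(pid, {})[cond] = dev
    return pd.DataFrame.from_dict(out, orient="index")[list(CONDITION_LABELS)]


def stats_report(tables: dict[str, pd.DataFrame], *, n_boot: int = 1_000_000,
                 seed: int | None = None) -> pd.DataFrame:
    """ANOVA + planned comparisons for every epoch table, as one tidy table."""
    rows = []
    for i, (epoch, table) in enumerate(tables.items()):
        sub_seed = None if seed is None else seed + i
        anova, comps = analyze_epoch_table(table, n_boot=n_boot, seed=sub_seed)
        for res in anova.values():
            rows.append(dict(epoch=epoch, kind="anova", term=res.effect,
                             F=res.F, df1=res.df[0], df2=res.df[1], p=res.p,
                             p_holm=np.nan, theta_hat=np.nan, diff=np.nan))
        for comp in comps:
            rows.append(dict(epoch=epoch, kind="comparison", term=comp.label,
                             F=np.nan, df1=np.nan, df2=np.nan, p=comp.p_raw,
                             p_holm=comp.p_holm, theta_hat=comp.theta_hat,
                             diff=comp.mean_difference))
    return pd.DataFrame(rows)
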