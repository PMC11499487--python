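"""Summaries of interaction networks across ordered disease stages.

Given the per-stage interaction records, this module counts significant
interactions per stage and per death mode, classifies per-mode gains and
losses between consecutive stages, and extracts per-cell-type Mantel-R
trajectories for a chosen mode.  "Significant" for counting means adjusted
p <= 0.05; the strength flag (R > 0.5) is carried along in the records so a
stricter rule is a one-line filter.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .io import ValidationError

__all__ = ["count_interactions", "classify_changes", "strength_trajectory"]


def count_interactions(records: pd.DataFrame,
                       stage_order: Sequence[str]) -> pd.DataFrame:
    """Per-stage totals and per-mode counts of significant interactions.

    Returns a DataFrame indexed by stage (in the declared order) with one
    column per death mode plus ``total``; row sums over modes equal the
    total by construction.
    """
    stage_order = list(stage_order)
    unknown = set(records["stage"].astype(str)) - set(stage_order)
    if unknown:
        raise ValidationError(f"records carry unknown stage labels: {sorted(unknown)}")
    modes = sorted(records["death_mode"].unique()) if len(records) else []
    out = pd.DataFrame(0, index=pd.Index(stage_order, name="stage"),
                       columns=modes, dtype=int)
    sig = records[records["significant"].astype(bool)] if len(records) else records
    for (stage, mode), group in sig.groupby(["stage", "death_mode"], observed=True):
        out.loc[str(stage), mode] = len(group)
    out["total"] = out.sum(axis=1)
    return out


def classify_changes(summaries: pd.DataFrame,
                     stage_order: Sequence[str]) -> pd.DataFrame:
    """Per-mode count changes between consecutive stages.

    ``delta = count_to - count_from`` with direction
    increase/decrease/unchanged.  Every declared stage must be present in
    the summary table.
    """
    stage_order = list(stage_order)
    if len(stage_order) < 2:
        raise ValidationError("need >= 2 stages to classify changes")
    missing = [s for s in stage_order if s not in summaries.index]
    if missing:
        raise ValidationError(f"summaries missing stage(s): {missing}")
    modes = [c for c in summaries.columns if c != "total"]
    rows = []
    for frm, to in zip(stage_order[:-1], stage_order[1:]):
        for mode in modes:
            delta = int(summaries.loc[to, mode]) - int(summaries.loc[frm, mode])
            direction = ("increase" if delta > 0
                         else "decrease" if delta < 0 else "unchanged")
            rows.append((mode, frm, to, delta, direction))
    return pd.DataFrame(rows, columns=["mode", "stage_from", "stage_to",
                                       "delta", "direction"])


def strength_trajectory(records: pd.DataFrame, mode: str,
                        stage_order: Sequence[str]) -> pd.DataFrame:
    """Cell-type x stage matrix of Mantel R for one death mode.

    Stages without a record for the mode (e.g. skipped for too few samples)
    are left as NaN.
    """
    stage_order = list(stage_order)
    subset = records[records["death_mode"] == mode]
    if len(subset) == 0:
        raise ValidationError(f"no records for mode {mode!r}")
    cell_types = list(dict.fromkeys(subset["cell_type"]))
    out = pd.DataFrame(np.nan, index=pd.Index(cell_types, name="cell_type"),
                       columns=stage_order)
    for _, row in subset.iterrows():
        if str(row["stage"]) in out.columns:
            out.loc[row["cell_type"], str(row["stage"])] = row["mantel_r"]
    return out
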