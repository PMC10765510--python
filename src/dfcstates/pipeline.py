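"""End-to-end orchestration: runs -> pooled windows -> states -> metrics -> graphs -> stats.

Thin glue over the per-stage modules so the CLI, the examples and scripted
analyses share one code path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clustering import StateModel, kmeans_states, pool_windows, state_metrics
from .graphs import INDICATOR_NAMES, binarize, dynamic_indicators, indicators
from .io import RoiTimeSeries
from .stats import group_compare, per_participant_change
from .windows import DfcSeries, WindowSpec, static_fc


@dataclass
class StatePipelineResult:
    """Everything the state analysis produces for one cohort."""

    model: StateModel
    features: np.ndarray
    provenance: pd.DataFrame
    dfc: list[DfcSeries]
    metrics: pd.DataFrame
    window_spec: WindowSpec


def run_state_pipeline(runs: list[RoiTimeSeries], window_seconds: float = 60.0,
                       step_tr: int = 1, k: int = 2, restarts: int = 10,
                       seed: int = 0) -> StatePipelineResult:
    """Pool windows of all runs, fit the shared K-means state model and
    compute the per-(participant, session, state) metrics."""
    spec = WindowSpec(window_seconds, step_tr)
    features, prov, dfc = pool_windows(runs, spec)
    model = kmeans_states(features, k, restarts, seed, roi_names=runs[0].roi_names)
    metrics = state_metrics(model, prov, features)
    return StatePipelineResult(model, features, prov, dfc, metrics, spec)


def static_indicator_table(runs: list[RoiTimeSeries], mode: str = "density",
                           value: float = 0.15, exclude_negative: bool = True,
                           ) -> pd.DataFrame:
    """One row of the six graph indicators per run's static FC."""
    rows = []
    for run in runs:
        ind = indicators(binarize(static_fc(run), mode, value, exclude_negative))
        rows.append((run.participant_id, run.session, run.run_id, *ind.as_dict().values()))
    return pd.DataFrame(rows, columns=["participant_id", "session", "run_id",
                                       *INDICATOR_NAMES])


def dynamic_indicator_table(dfc_list: list[DfcSeries], mode: str = "density",
                            value: float = 0.15, exclude_negative: bool = True,
                            ) -> pd.DataFrame:
    """One row of the six indicators per dFC window across all runs."""
    frames = []
    for dfc in dfc_list:
        f = dynamic_indicators(dfc, mode, value, exclude_negative).to_frame()
        pid, session, run_id = dfc.source
        f.insert(0, "run_id", run_id)
        f.insert(0, "session", session)
        f.insert(0, "participant_id", pid)
        frames.append(f)
    return pd.concat(frames, ignore_index=True)


def session_state_table(metrics: pd.DataFrame, state: int) -> pd.DataFrame:
    """Slice the metrics table down to one state, ready for group_compare."""
    cols = ["strength", "occupancy_rate", "dwell_time_seconds", "transitions_per_minute"]
    return metrics.loc[metrics["state"] == state,
                       ["participant_id", "session", *cols]].reset_index(drop=True)


def compare_state_metrics(metrics: pd.DataFrame, alpha: float = 0.05,
                          correction: str = "none", paired: bool = False) -> pd.DataFrame:
    """Group pre/post tests for every state's strength/occupancy/dwell/transitions."""
    frames = []
    for state in sorted(metrics["state"].unique()):
        table = session_state_table(metrics, state)
        res = group_compare(table, ["strength", "occupancy_rate",
                                    "dwell_time_seconds", "transitions_per_minute"],
                            alpha=alpha, correction=correction, paired=paired)
        res.insert(0, "state", state)
        frames.append(res)
    return pd.concat(frames, ignore_index=True)


def compare_graph_indicators(indicator_table: pd.DataFrame, alpha: float = 0.05,
                             correction: str = "none", paired: bool = False) -> pd.DataFrame:
    """Group pre/post tests over the six static indicators (Table-1 layout)."""
    return group_compare(indicator_table, INDICATOR_NAMES, alpha=alpha,
                         correction=correction, paired=paired)


def tally_dynamic_changes(dynamic_table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Per-participant window-level tests tallied per indicator (Table-2 layout)."""
    return per_participant_change(dynamic_table, INDICATOR_NAMES, alpha=alpha)
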