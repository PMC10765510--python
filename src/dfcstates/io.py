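"""Input/output: ROI time-series tables, run manifests, lobe maps, result tables, config.

All tabular inputs are delimited text (comma or tab, sniffed) with a mandatory
header row. A run manifest ties each time-series file to its participant,
session (``pre_op``/``post_op``), run id and repetition time (TR, seconds); TR
is never inferred from data.
"""

from __future__ import annotations

import csv
import dataclasses
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Iterable

import numpy as np
import pandas as pd
import yaml

from .errors import LoadError, SchemaError

SESSIONS = ("pre_op", "post_op")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class RoiTimeSeries:
    """One run's parcellated signals: a T x N matrix plus acquisition metadata.

    Parameters
    ----------
    data
        Array of shape (T, N), one row per time point, one column per ROI.
    roi_names
        N unique ROI labels, in column order.
    tr_seconds
        Repetition time of the acquisition, in seconds (> 0).
    participant_id, session, run_id
        Provenance; ``session`` is one of ``pre_op``/``post_op``.
    """

    data: np.ndarray
    roi_names: list[str]
    tr_seconds: float
    participant_id: str = "unknown"
    session: str = "pre_op"
    run_id: str = "run-1"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.roi_names = [str(r) for r in self.roi_names]
        if self.data.ndim != 2:
            raise SchemaError("time-series data must be a 2-D (T x N) array")
        t, n = self.data.shape
        if t < 2 or n < 2:
            raise SchemaError(f"need T >= 2 time points and N >= 2 ROIs, got T={t}, N={n}")
        if len(self.roi_names) != n:
            raise SchemaError(f"{len(self.roi_names)} ROI names for {n} columns")
        if len(set(self.roi_names)) != n:
            dupes = sorted({r for r in self.roi_names if self.roi_names.count(r) > 1})
            raise SchemaError(f"duplicate ROI names: {dupes}")
        if not np.isfinite(self.data).all():
            bad = np.argwhere(~np.isfinite(self.data))[0]
            raise LoadError(
                f"missing/non-finite value at row {bad[0]}, column {self.roi_names[bad[1]]!r}"
            )
        if not (self.tr_seconds > 0):
            raise SchemaError(f"tr_seconds must be > 0, got {self.tr_seconds}")
        if self.session not in SESSIONS:
            raise SchemaError(f"session must be one of {SESSIONS}, got {self.session!r}")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.participant_id, self.session, self.run_id)


@dataclass(frozen=True)
class ManifestEntry:
    participant_id: str
    session: str
    run_id: str
    tr_seconds: float
    path: str

    def __post_init__(self) -> None:
        if self.session not in SESSIONS:
            raise SchemaError(f"session must be one of {SESSIONS}, got {self.session!r}")
        if not (float(self.tr_seconds) > 0):
            raise SchemaError(f"tr_seconds must be > 0, got {self.tr_seconds}")


@dataclass
class RunManifest:
    """Ordered list of runs to analyse; (participant, session, run) triples are unique."""

    entries: list[ManifestEntry]

    def __post_init__(self) -> None:
        keys = [(e.participant_id, e.session, e.run_id) for e in self.entries]
        if len(set(keys)) != len(keys):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise SchemaError(f"duplicate (participant, session, run) triples: {dupes}")

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class LobeMap:
    """ROI label -> lobe label mapping; ``lobes`` keeps first-appearance order."""

    roi_to_lobe: dict[str, str]
    lobes: list[str]

    def __post_init__(self) -> None:
        if not self.roi_to_lobe:
            raise SchemaError("lobe map is empty")
        missing = [l for l in self.roi_to_lobe.values() if l not in self.lobes]
        if missing:
            raise SchemaError(f"lobes {sorted(set(missing))} used but not listed")

    def lobe_of(self, roi: str) -> str:
        return self.roi_to_lobe[roi]


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

def _sniff_delimiter(path: Path) -> str:
    sample = Path(path).read_text(encoding="utf-8")[:8192]
    if not sample.strip():
        raise SchemaError(f"{path}: file is empty")
    try:
        return csv.Sniffer().sniff(sample, delimiters=",\t").delimiter
    except csv.Error:
        return ","


def load_timeseries(path: str | Path, manifest_entry: ManifestEntry | None = None,
                    *, tr_seconds: float | None = None) -> RoiTimeSeries:
    """Load a delimited table (header = ROI names, rows = time points).

    Missing or non-numeric cells raise :class:`LoadError` naming the row and
    column; duplicate ROI names raise :class:`SchemaError`.
    """
    path = Path(path)
    delim = _sniff_delimiter(path)
    with open(path, newline="", encoding="utf-8") as fh:
        header = next(csv.reader(fh, delimiter=delim))
    roi_names = [h.strip() for h in header]
    if len(set(roi_names)) != len(roi_names):
        raise SchemaError(f"{path}: duplicate ROI names in header")
    raw = pd.read_csv(path, sep=delim, header=None, names=roi_names, skiprows=1, dtype=str)
    if raw.shape[0] < 2:
        raise SchemaError(f"{path}: need at least 2 data rows, got {raw.shape[0]}")
    values = raw.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    if not np.isfinite(values).all():
        r, c = np.argwhere(~np.isfinite(values))[0]
        raise LoadError(f"{path}: missing or non-numeric cell at data row {r}, column {roi_names[c]!r}")
    if manifest_entry is not None:
        return RoiTimeSeries(values, roi_names, float(manifest_entry.tr_seconds),
                             manifest_entry.participant_id, manifest_entry.session,
                             manifest_entry.run_id)
    if tr_seconds is None:
        raise SchemaError("tr_seconds required when no manifest entry is given")
    return RoiTimeSeries(values, roi_names, float(tr_seconds))


def load_manifest(path: str | Path) -> RunManifest:
    """Load a manifest CSV with columns participant_id, session, run_id, tr_seconds, path.

    Relative ``path`` values are resolved against the manifest's directory.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_delimiter(path))
    required = ["participant_id", "session", "run_id", "tr_seconds", "path"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: manifest missing columns {missing}")
    entries = []
    for _, row in df.iterrows():
        p = Path(str(row["path"]))
        if not p.is_absolute():
            p = path.parent / p
        entries.append(ManifestEntry(str(row["participant_id"]), str(row["session"]),
                                     str(row["run_id"]), float(row["tr_seconds"]), str(p)))
    return RunManifest(entries)


def load_runs(manifest: RunManifest) -> list[RoiTimeSeries]:
    """Load every run referenced by a manifest."""
    return [load_timeseries(e.path, e) for e in manifest]


def load_lobe_map(path: str | Path) -> LobeMap:
    """Load a two-column (roi, lobe) table; lobes keep first-appearance order."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_delimiter(path))
    if df.shape[1] < 2 or df.shape[0] == 0:
        raise SchemaError(f"{path}: expected a non-empty two-column (roi, lobe) table")
    roi_col, lobe_col = df.columns[:2]
    mapping: dict[str, str] = {}
    lobes: list[str] = []
    for _, row in df.iterrows():
        roi, lobe = str(row[roi_col]).strip(), str(row[lobe_col]).strip()
        if roi in mapping and mapping[roi] != lobe:
            raise SchemaError(f"{path}: ROI {roi!r} mapped to both {mapping[roi]!r} and {lobe!r}")
        mapping[roi] = lobe
        if lobe not in lobes:
            lobes.append(lobe)
    return LobeMap(mapping, lobes)


def default_lobe_map() -> LobeMap:
    """The shipped AAL-116 -> six-lobe assignment (frontal, occipital, parietal,
    subcortical, temporal, cerebellum). The table is data, not code: it can be
    copied and edited for other atlases or grouping conventions."""
    with resources.as_file(resources.files("dfcstates.data") / "aal116_lobes.csv") as p:
        return load_lobe_map(p)


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def write_report(results: Any, path: str | Path) -> None:
    """Write a pipeline product: DataFrames as CSV, anything else as JSON.

    CSV writing uses shortest-round-trip float formatting, so tables reload
    to at least 12 significant digits (in fact exactly).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(results, pd.DataFrame):
        results.to_csv(path, index=False)
        return
    if dataclasses.is_dataclass(results) and not isinstance(results, type):
        results = dataclasses.asdict(results)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(_jsonable(results), fh, indent=2)
        fh.write("\n")


def read_report(path: str | Path) -> pd.DataFrame:
    """Reload a tabular report written by :func:`write_report`."""
    return pd.read_csv(path)


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    return obj


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

DEFAULT_CONFIG: dict[str, dict[str, Any]] = {
    "windows": {"window_seconds": 60.0, "step_tr": 1},
    "clustering": {"k": 2, "restarts": 10},
    "graphs": {"threshold_mode": "density", "threshold": 0.15, "exclude_negative": True},
    "stats": {"alpha": 0.05, "correction": "none", "paired": False},
    "simulate": {"participants": 20, "scenario": "paper_like", "tr": 2.0},
}


def load_config(path: str | Path | None = None) -> dict[str, dict[str, Any]]:
    """Load a YAML config with sections windows/clustering/graphs/stats/simulate,
    merged over the package defaults."""
    config = {k: dict(v) for k, v in DEFAULT_CONFIG.items()}
    if path is not None:
        with open(path, encoding="utf-8") as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise SchemaError(f"{path}: config must be a mapping of sections")
        for section, values in user.items():
            if section not in config:
                raise SchemaError(f"{path}: unknown config section {section!r}")
            config[section].update(values or {})
    return config
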