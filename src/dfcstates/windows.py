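"""Static and sliding-window functional connectivity.

A run's static FC is the Pearson correlation matrix over the whole series;
dynamic FC (dFC) is the ordered sequence of Pearson matrices over boxcar
windows of a fixed length (specified in seconds, converted to whole TRs,
ties rounding up) advanced by a whole-TR step. Windows use 0-based,
half-open [start_tr, end_tr) coordinates and never cross run boundaries.
No Fisher z-transform, tapering or within-window detrending is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateInputError, InputTooShortError, SchemaError
from .io import RoiTimeSeries


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window parameters: length in seconds, step in TRs."""

    length_seconds: float = 60.0
    step_tr: int = 1

    def __post_init__(self) -> None:
        if not (self.length_seconds > 0):
            raise SchemaError(f"window length must be > 0 s, got {self.length_seconds}")
        if int(self.step_tr) != self.step_tr or self.step_tr < 1:
            raise SchemaError(f"step_tr must be an integer >= 1, got {self.step_tr}")

    def length_tr(self, tr_seconds: float) -> int:
        """Window length in whole TRs: nearest integer, ties rounded up."""
        n = math.floor(self.length_seconds / tr_seconds + 0.5)
        if n < 2:
            raise SchemaError(
                f"window of {self.length_seconds} s is {n} TR at TR={tr_seconds} s; need >= 2"
            )
        return n


@dataclass
class FcMatrix:
    """An N x N Pearson correlation matrix with optional window provenance."""

    values: np.ndarray
    roi_names: list[str]
    window_index: int | None = None
    start_tr: int | None = None
    end_tr: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.roi_names)
        if self.values.shape != (n, n):
            raise SchemaError(f"FC matrix shape {self.values.shape} != ({n}, {n})")
        if not np.allclose(self.values, self.values.T, atol=1e-12, rtol=0):
            raise SchemaError("FC matrix not symmetric")
        if not np.all(np.diag(self.values) == 1.0):
            raise SchemaError("FC matrix diagonal must be exactly 1")
        if np.abs(self.values).max() > 1.0:
            raise SchemaError("FC entries must lie in [-1, 1]")

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]


@dataclass
class DfcSeries:
    """Ordered per-window FC matrices for one run."""

    windows: list[FcMatrix]
    source: tuple[str, str, str]
    window_spec: WindowSpec
    tr_seconds: float

    def __len__(self) -> int:
        return len(self.windows)

    @property
    def roi_names(self) -> list[str]:
        return self.windows[0].roi_names

    def feature_matrix(self) -> np.ndarray:
        """Stacked upper-triangle vectors, shape (n_windows, N(N-1)/2)."""
        return np.stack([vectorize_upper(w) for w in self.windows])


def window_count(t: int, length_tr: int, step_tr: int) -> int:
    """Number of boxcar windows: floor((T - L) / step) + 1."""
    return (t - length_tr) // step_tr + 1


def _pearson(block: np.ndarray, roi_names: list[str], context: str) -> np.ndarray:
    sd = block.std(axis=0)
    if np.any(sd == 0):
        roi = roi_names[int(np.argmax(sd == 0))]
        raise DegenerateInputError(f"zero-variance ROI {roi!r} {context}")
    r = np.corrcoef(block, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return r


def static_fc(run: RoiTimeSeries) -> FcMatrix:
    """Pearson correlation over the entire run (the sFC matrix)."""
    return FcMatrix(_pearson(run.data, run.roi_names, "over the full run"), run.roi_names)


def sliding_windows(run: RoiTimeSeries, spec: WindowSpec = WindowSpec()) -> DfcSeries:
    """Per-window Pearson matrices over boxcar windows (the dFC series)."""
    length = spec.length_tr(run.tr_seconds)
    t = run.n_timepoints
    if t < length:
        raise InputTooShortError(
            f"run {run.key}: T={t} shorter than window of {length} TR"
        )
    mats = []
    for w in range(window_count(t, length, spec.step_tr)):
        start = w * spec.step_tr
        try:
            r = _pearson(run.data[start:start + length], run.roi_names, f"in window {w}")
        except DegenerateInputError as err:
            raise DegenerateInputError(f"run {run.key}: {err}") from None
        mats.append(FcMatrix(r, run.roi_names, window_index=w,
                             start_tr=start, end_tr=start + length))
    return DfcSeries(mats, run.key, spec, run.tr_seconds)


def vectorize_upper(fc: FcMatrix | np.ndarray) -> np.ndarray:
    """Row-major upper triangle (diagonal excluded), length N(N-1)/2."""
    m = fc.values if isinstance(fc, FcMatrix) else np.asarray(fc, dtype=float)
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu].copy()


def devectorize_upper(vec: np.ndarray, roi_names: list[str]) -> FcMatrix:
    """Inverse of :func:`vectorize_upper`: rebuild the symmetric unit-diagonal matrix."""
    n = len(roi_names)
    if len(vec) != n * (n - 1) // 2:
        raise SchemaError(f"vector length {len(vec)} != N(N-1)/2 for N={n}")
    m = np.eye(n)
    iu = np.triu_indices(n, k=1)
    m[iu] = vec
    m[(iu[1], iu[0])] = vec
    return FcMatrix(np.clip(m, -1.0, 1.0), list(roi_names))
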