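"""Brain-state identification: pooled K-means over dFC windows, cluster-quality
criteria, state metrics, and lobe-level centroid summaries.

All windows of all participants and both sessions are clustered together in a
single Euclidean K-means over upper-triangle FC vectors; states are then
canonically ordered by descending centroid strength (state 1 = strongest), and
per-(participant, session) metrics are obtained by slicing the shared labels.

Quality criteria
----------------
Three internal validity indices are computed from the samples and labels with
Euclidean dissimilarity:

* silhouette: s_i = (b_i - a_i) / max(a_i, b_i), averaged over samples, where
  a_i is the mean distance of sample i to the other members of its cluster and
  b_i the minimum over other clusters of the mean distance to their members;
* Calinski-Harabasz: [sum_k n_k ||z_k - z||^2 / (K-1)] / [sum_i ||x_i - z_{k(i)}||^2 / (n-K)];
* Davies-Bouldin: (1/K) sum_i max_{j != i} (s_i + s_j) / d_ij with s_i the mean
  member-to-centroid distance and d_ij the centroid separation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, MappingError, SchemaError
from .io import LobeMap, RoiTimeSeries
from .windows import DfcSeries, FcMatrix, WindowSpec, devectorize_upper, sliding_windows


# ---------------------------------------------------------------------------
# pooling
# ---------------------------------------------------------------------------

def pool_windows(runs: list[RoiTimeSeries], spec: WindowSpec = WindowSpec(),
                 ) -> tuple[np.ndarray, pd.DataFrame, list[DfcSeries]]:
    """Window every run and stack all upper-triangle vectors.

    Returns (features, provenance, dfc_list) where ``features`` is
    (n_windows_total, N(N-1)/2) and ``provenance`` has one row per pooled
    window: participant_id, session, run_id, window_index, tr_seconds, step_tr.
    """
    feats, rows, series = [], [], []
    for run in runs:
        dfc = sliding_windows(run, spec)
        series.append(dfc)
        feats.append(dfc.feature_matrix())
        for w in dfc.windows:
            rows.append((run.participant_id, run.session, run.run_id,
                         w.window_index, run.tr_seconds, spec.step_tr))
    prov = pd.DataFrame(rows, columns=["participant_id", "session", "run_id",
                                       "window_index", "tr_seconds", "step_tr"])
    return np.vstack(feats), prov, series


# ---------------------------------------------------------------------------
# K-means
# ---------------------------------------------------------------------------

@dataclass
class StateModel:
    """Fitted state model: centroid vectors (and, when the features are FC
    upper triangles, centroid FC matrices), per-window labels, inertia."""

    k: int
    centers: np.ndarray
    labels: np.ndarray
    inertia: float
    seed: int
    restarts: int
    roi_names: list[str] | None = None
    centroids: list[FcMatrix] | None = None

    def __post_init__(self) -> None:
        counts = np.bincount(self.labels, minlength=self.k)
        if (counts == 0).any():
            raise SchemaError("every state must be nonempty")

    def centroid_vectors(self) -> np.ndarray:
        return self.centers

    def centroid_strengths(self) -> np.ndarray:
        """Mean feature (upper-triangle r) of each centroid (descending by
        construction)."""
        return self.centers.mean(axis=1)


def _assign(x: np.ndarray, centers: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Squared distances to centers and nearest-center labels (ties -> lower index)."""
    d2 = (x * x).sum(1)[:, None] - 2.0 * (x @ centers.T) + (centers * centers).sum(1)[None, :]
    np.maximum(d2, 0.0, out=d2)
    return d2, d2.argmin(axis=1)


def _lloyd(x: np.ndarray, k: int, rng: np.random.Generator,
           max_iter: int = 300) -> tuple[np.ndarray, np.ndarray, float]:
    centers = x[rng.choice(x.shape[0], size=k, replace=False)].copy()
    labels = np.full(x.shape[0], -1)
    for _ in range(max_iter):
        d2, new_labels = _assign(x, centers)
        for j in np.flatnonzero(np.bincount(new_labels, minlength=k) == 0):
            # deterministic empty-cluster repair: take the worst-fit sample
            far = int(d2[np.arange(len(new_labels)), new_labels].argmax())
            centers[j] = x[far]
            new_labels[far] = j
            d2[far] = 0.0
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for j in range(k):
            centers[j] = x[labels == j].mean(axis=0)
    d2, labels = _assign(x, centers)
    inertia = float(d2[np.arange(len(labels)), labels].sum())
    return centers, labels, inertia


def kmeans_states(features: np.ndarray, k: int, restarts: int = 10, seed: int = 0,
                  roi_names: list[str] | None = None) -> StateModel:
    """Best-of-``restarts`` Lloyd K-means with centroids initialised uniformly
    at random from the data points; states reordered by descending strength."""
    x = np.asarray(features, dtype=float)
    if x.ndim != 2 or x.shape[0] < k:
        raise SchemaError(f"need at least k={k} windows, got {x.shape[0]}")
    if restarts < 1:
        raise SchemaError("restarts must be >= 1")
    if np.unique(x, axis=0).shape[0] < k:
        raise DegenerateInputError(f"fewer than k={k} distinct windows")
    rng = np.random.default_rng(seed)
    best: tuple[np.ndarray, np.ndarray, float] | None = None
    for _ in range(restarts):
        centers, labels, inertia = _lloyd(x, k, rng)
        if best is None or inertia < best[2]:
            best = (centers, labels, inertia)
    centers, labels, inertia = best
    order = np.argsort(-centers.mean(axis=1), kind="stable")
    centers = centers[order]
    relabel = np.empty(k, dtype=np.int64)
    relabel[order] = np.arange(k)
    labels = relabel[labels]
    cents = None
    if roi_names is None:
        n = int(round((1 + np.sqrt(1 + 8 * x.shape[1])) / 2))
        if n * (n - 1) // 2 == x.shape[1] and np.abs(centers).max() <= 1.0:
            roi_names = [f"roi{i + 1:03d}" for i in range(n)]
    if roi_names is not None:
        cents = [devectorize_upper(c, list(roi_names)) for c in centers]
    return StateModel(k, centers, labels, inertia, int(seed), int(restarts),
                      list(roi_names) if roi_names is not None else None, cents)


# ---------------------------------------------------------------------------
# quality criteria
# ---------------------------------------------------------------------------

@dataclass
class ClusterQualityReport:
    """Internal validity indices for one parameter setting."""

    parameter: tuple[str, object] | None
    k: int
    inertia: float
    silhouette: float
    calinski_harabasz: float
    davies_bouldin: float
    error: str | None = None


def _pairwise_cluster_stats(x: np.ndarray, labels: np.ndarray, k: int,
                            chunk: int = 2048) -> np.ndarray:
    """Sum of Euclidean distances from each sample to every cluster, (n, k).

    Distances are formed from explicit differences (cdist), not the expanded
    dot-product identity, so the silhouette is accurate to ~1e-13."""
    from scipy.spatial.distance import cdist
    n = x.shape[0]
    sums = np.empty((n, k))
    members = [x[labels == j] for j in range(k)]
    for start in range(0, n, chunk):
        xs = x[start:start + chunk]
        for j in range(k):
            sums[start:start + chunk, j] = cdist(xs, members[j]).sum(axis=1)
    return sums


def quality_criteria(features: np.ndarray, labels: np.ndarray,
                     parameter: tuple[str, object] | None = None) -> ClusterQualityReport:
    """Silhouette, Calinski-Harabasz and Davies-Bouldin for one labelling."""
    x = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    k = len(uniq)
    if k < 2:
        raise SchemaError("quality criteria need >= 2 clusters")
    relabel = {u: i for i, u in enumerate(uniq)}
    labels = np.array([relabel[u] for u in labels])
    counts = np.bincount(labels, minlength=k)
    if counts.max() < 2:
        raise DegenerateInputError("silhouette undefined: all clusters are singletons")
    n = x.shape[0]
    centroids = np.stack([x[labels == j].mean(axis=0) for j in range(k)])
    # inertia and CH
    diffs = x - centroids[labels]
    within = float((diffs * diffs).sum())
    grand = x.mean(axis=0)
    between = float((counts * ((centroids - grand) ** 2).sum(axis=1)).sum())
    ch = (between / (k - 1)) / (within / (n - k)) if within > 0 else np.inf
    # silhouette
    dist_sums = _pairwise_cluster_stats(x, labels, k)
    own = counts[labels]
    sil = np.zeros(n)
    nontrivial = own > 1
    a = np.where(nontrivial, dist_sums[np.arange(n), labels] / np.maximum(own - 1, 1), 0.0)
    mean_other = dist_sums / counts[None, :]
    mean_other[np.arange(n), labels] = np.inf
    b = mean_other.min(axis=1)
    denom = np.maximum(a, b)
    sil[nontrivial] = ((b - a) / np.where(denom > 0, denom, 1.0))[nontrivial]
    silhouette = float(sil.mean())
    # Davies-Bouldin
    s = np.array([np.sqrt(((x[labels == j] - centroids[j]) ** 2).sum(axis=1)).mean()
                  for j in range(k)])
    cd = np.sqrt(((centroids[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (s[:, None] + s[None, :]) / cd
    np.fill_diagonal(r, -np.inf)
    db = float(np.max(r, axis=1).mean())
    return ClusterQualityReport(parameter, k, within, silhouette, float(ch), db)


# ---------------------------------------------------------------------------
# parameter sweep
# ---------------------------------------------------------------------------

def sweep(parameter: str, grid: list, runs: list[RoiTimeSeries], *,
          window_seconds: float = 60.0, step_tr: int = 1, k: int = 2,
          restarts: int = 10, seed: int = 0,
          silhouette_sample_size: int | None = None) -> list[ClusterQualityReport]:
    """Evaluate clustering quality along one parameter grid
    (``window_seconds``, ``step_tr`` or ``k``), other settings fixed.

    Per-value failures are recorded in the report's ``error`` field and the
    sweep continues. For large pooled window sets the silhouette may be
    evaluated on a seeded subsample (``silhouette_sample_size``); inertia, CH
    and DB are always exact.
    """
    if parameter not in ("window_seconds", "step_tr", "k"):
        raise SchemaError(f"unknown sweep parameter {parameter!r}")
    if not len(grid):
        raise SchemaError("sweep grid is empty")
    reports: list[ClusterQualityReport] = []
    cache: dict[tuple[float, int], np.ndarray] = {}

    def pooled(ws: float, st: int) -> np.ndarray:
        key = (ws, st)
        if key not in cache:
            cache[key] = pool_windows(runs, WindowSpec(ws, st))[0]
        return cache[key]

    for value in grid:
        settings = {"window_seconds": window_seconds, "step_tr": step_tr, "k": k}
        settings[parameter] = value
        try:
            x = pooled(float(settings["window_seconds"]), int(settings["step_tr"]))
            model = kmeans_states(x, int(settings["k"]), restarts, seed)
            labels = model.labels
            if silhouette_sample_size is not None and x.shape[0] > silhouette_sample_size:
                sub = np.random.default_rng(seed).choice(
                    x.shape[0], size=silhouette_sample_size, replace=False)
                rep_sub = quality_criteria(x[sub], labels[sub], (parameter, value))
                rep = quality_criteria_from_model(x, model, (parameter, value))
                rep.silhouette = rep_sub.silhouette
            else:
                rep = quality_criteria(x, labels, (parameter, value))
            rep.inertia = model.inertia
            reports.append(rep)
        except Exception as err:  # per-value error, sweep continues
            reports.append(ClusterQualityReport((parameter, value), int(settings["k"]),
                                                np.nan, np.nan, np.nan, np.nan, str(err)))
    return reports


def quality_criteria_from_model(x: np.ndarray, model: StateModel,
                                parameter=None) -> ClusterQualityReport:
    """CH/DB/inertia from a fitted model without the O(n^2) silhouette."""
    labels = model.labels
    k = model.k
    counts = np.bincount(labels, minlength=k)
    centroids = np.stack([x[labels == j].mean(axis=0) for j in range(k)])
    diffs = x - centroids[labels]
    within = float((diffs * diffs).sum())
    grand = x.mean(axis=0)
    between = float((counts * ((centroids - grand) ** 2).sum(axis=1)).sum())
    ch = (between / (k - 1)) / (within / (x.shape[0] - k)) if within > 0 else np.inf
    s = np.array([np.sqrt(((x[labels == j] - centroids[j]) ** 2).sum(axis=1)).mean()
                  for j in range(k)])
    cd = np.sqrt(((centroids[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (s[:, None] + s[None, :]) / cd
    np.fill_diagonal(r, -np.inf)
    db = float(np.max(r, axis=1).mean())
    return ClusterQualityReport(parameter, k, within, np.nan, float(ch), db)


def reports_to_frame(reports: list[ClusterQualityReport]) -> pd.DataFrame:
    rows = []
    for r in reports:
        name, value = r.parameter if r.parameter else ("", np.nan)
        rows.append((name, value, r.k, r.inertia, r.silhouette,
                     r.calinski_harabasz, r.davies_bouldin, r.error or ""))
    return pd.DataFrame(rows, columns=["parameter", "value", "k", "inertia",
                                       "silhouette", "calinski_harabasz",
                                       "davies_bouldin", "error"])


# ---------------------------------------------------------------------------
# state metrics
# ---------------------------------------------------------------------------

def state_metrics(model: StateModel, provenance: pd.DataFrame,
                  features: np.ndarray | None = None) -> pd.DataFrame:
    """Per-(participant, session, state) metrics from the shared labelling.

    occupancy_rate
        Windows in the state / total windows of that participant-session.
    dwell_time_seconds
        Mean length of maximal same-state window runs (never crossing run
        boundaries) x step_tr x TR. Missing (NaN) for unvisited states.
    transitions_per_minute
        Label changes / (total windows x step_tr x TR / 60), runs pooled
        by window count. Identical for all states of a participant-session.
    strength
        Mean r over the member windows' upper triangles (session-resolved);
        falls back to the centroid strength when ``features`` is None.
    """
    prov = provenance.reset_index(drop=True)
    labels = np.asarray(model.labels)
    if len(prov) != len(labels):
        raise SchemaError("provenance rows != number of labels")
    cent_strength = model.centroid_strengths()
    win_mean = features.mean(axis=1) if features is not None else None
    rows = []
    for (pid, session), g in prov.groupby(["participant_id", "session"], sort=True):
        idx = g.index.to_numpy()
        lab = labels[idx]
        total = len(idx)
        tr = float(g["tr_seconds"].iloc[0])
        step = int(g["step_tr"].iloc[0])
        seconds_per_window = step * tr
        changes = 0
        run_lengths: dict[int, list[int]] = {s: [] for s in range(model.k)}
        for _, gr in g.groupby("run_id", sort=True):
            lr = labels[gr.sort_values("window_index").index.to_numpy()]
            changes += int((lr[1:] != lr[:-1]).sum())
            bounds = np.flatnonzero(np.r_[True, lr[1:] != lr[:-1], True])
            for a, b in zip(bounds[:-1], bounds[1:]):
                run_lengths[int(lr[a])].append(int(b - a))
        tpm = changes / (total * seconds_per_window / 60.0)
        for s in range(model.k):
            n_s = int((lab == s).sum())
            occ = n_s / total
            dwell = (float(np.mean(run_lengths[s])) * seconds_per_window
                     if run_lengths[s] else np.nan)
            if n_s == 0:
                strength = np.nan
            elif win_mean is not None:
                strength = float(win_mean[idx[lab == s]].mean())
            else:
                strength = float(cent_strength[s])
            rows.append((pid, session, s, strength, occ, dwell, tpm, n_s))
    return pd.DataFrame(rows, columns=["participant_id", "session", "state", "strength",
                                       "occupancy_rate", "dwell_time_seconds",
                                       "transitions_per_minute", "n_windows"])


# ---------------------------------------------------------------------------
# lobe summaries
# ---------------------------------------------------------------------------

def lobe_summary(centroid: FcMatrix, lobe_map: LobeMap) -> pd.DataFrame:
    """Mean centroid r over every ROI pair spanning each lobe pair.

    Within-lobe entries average upper-triangle pairs only (no diagonal);
    the frame has one row per unordered lobe pair (lobe_i <= lobe_j in the
    lobe map's order)."""
    unmapped = [r for r in centroid.roi_names if r not in lobe_map.roi_to_lobe]
    if unmapped:
        raise MappingError(f"ROIs without lobe assignment: {unmapped[:5]}")
    lobes = lobe_map.lobes
    lobe_idx = {l: i for i, l in enumerate(lobes)}
    member = [np.array([lobe_idx[lobe_map.lobe_of(r)] == i for r in centroid.roi_names])
              for i in range(len(lobes))]
    m = centroid.values
    rows = []
    for i, li in enumerate(lobes):
        for j in range(i, len(lobes)):
            if i == j:
                sub = m[np.ix_(member[i], member[i])]
                iu = np.triu_indices(sub.shape[0], k=1)
                vals = sub[iu]
            else:
                vals = m[np.ix_(member[i], member[j])].ravel()
            rows.append((li, lobes[j], float(vals.mean()) if vals.size else np.nan))
    return pd.DataFrame(rows, columns=["lobe_i", "lobe_j", "mean_r"])


def lobe_difference(post: pd.DataFrame, pre: pd.DataFrame) -> pd.DataFrame:
    """Post-minus-pre lobe summary (aligned on lobe pairs)."""
    merged = post.merge(pre, on=["lobe_i", "lobe_j"], suffixes=("_post", "_pre"))
    merged["mean_r"] = merged["mean_r_post"] - merged["mean_r_pre"]
    return merged[["lobe_i", "lobe_j", "mean_r"]]
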