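"""Synthetic multi-ROI time series with planted connectivity states.

The generator draws a hidden per-TR state sequence from a first-order Markov
chain and, given the state, samples each time point from a zero-mean
multivariate normal with that state's covariance (optionally AR(1)-smoothed).
State covariances are block "lobe" correlation matrices: a strongly connected
regime and a sparsely connected regime. A cohort scenario pairs a pre-op and
a post-op condition; the default post-op condition plants the stimulation
effect the downstream pipeline is meant to detect — uniformly weaker
correlations in both states and switching that favours the sparse state.

Everything is reproducible: identical seeds give bit-identical outputs, and
analytic ground truth (per-TR labels, stationary occupancy, mean sojourn
1/(1 - p_kk)) accompanies every simulated run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import GenerationError, SchemaError
from .io import LobeMap, ManifestEntry, RoiTimeSeries, RunManifest, write_report


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass
class StateSpec:
    """A connectivity state: a symmetric positive-definite covariance matrix."""

    name: str
    covariance: np.ndarray
    description: str | None = None

    def __post_init__(self) -> None:
        self.covariance = np.asarray(self.covariance, dtype=float)
        c = self.covariance
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise SchemaError(f"covariance must be square, got shape {c.shape}")
        if np.abs(c - c.T).max() > 1e-10:
            raise SchemaError("covariance not symmetric (tolerance 1e-10)")
        if np.linalg.eigvalsh(c).min() <= 0:
            raise SchemaError(f"covariance of state {self.name!r} is not positive definite")

    @property
    def n_rois(self) -> int:
        return self.covariance.shape[0]

    def correlation(self) -> np.ndarray:
        d = np.sqrt(np.diag(self.covariance))
        return self.covariance / np.outer(d, d)


@dataclass
class SwitchingSpec:
    """Per-TR Markov switching: row-stochastic transition matrix + initial law."""

    transition_matrix: np.ndarray
    initial_distribution: np.ndarray | None = None

    def __post_init__(self) -> None:
        p = np.asarray(self.transition_matrix, dtype=float)
        if p.ndim != 2 or p.shape[0] != p.shape[1]:
            raise SchemaError("transition matrix must be square")
        if (p < 0).any() or np.abs(p.sum(axis=1) - 1.0).max() > 1e-12:
            raise SchemaError("transition matrix rows must be nonnegative and sum to 1")
        self.transition_matrix = p
        if self.initial_distribution is None:
            self.initial_distribution = self.stationary_distribution()
        pi = np.asarray(self.initial_distribution, dtype=float)
        if (pi < 0).any() or abs(pi.sum() - 1.0) > 1e-12 or len(pi) != p.shape[0]:
            raise SchemaError("initial distribution must be a length-K probability vector")
        self.initial_distribution = pi

    @property
    def n_states(self) -> int:
        return self.transition_matrix.shape[0]

    def stationary_distribution(self) -> np.ndarray:
        """Left eigenvector of P for eigenvalue 1, normalised to sum 1."""
        p = self.transition_matrix
        vals, vecs = np.linalg.eig(p.T)
        k = int(np.argmin(np.abs(vals - 1.0)))
        pi = np.real(vecs[:, k])
        pi = np.abs(pi)
        return pi / pi.sum()

    def mean_sojourn_tr(self) -> np.ndarray:
        """Geometric mean sojourn per state, 1 / (1 - p_kk), in TRs
        (inf for an absorbing state)."""
        with np.errstate(divide="ignore"):
            return 1.0 / (1.0 - np.diag(self.transition_matrix))


@dataclass
class SimulationGroundTruth:
    """Per-TR hidden labels plus the chain's analytic occupancy and sojourn."""

    state_labels_per_tr: np.ndarray
    true_occupancy: np.ndarray
    true_mean_sojourn_tr: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        if abs(float(np.sum(self.true_occupancy)) - 1.0) > 1e-12:
            raise SchemaError("true occupancy must sum to 1")


# ---------------------------------------------------------------------------
# covariance construction
# ---------------------------------------------------------------------------

def make_block_covariance(n_rois: int, lobe_sizes: list[int], within_r: float,
                          between_r: float, jitter: float = 0.0,
                          seed: int = 0, name: str = "state") -> StateSpec:
    """Unit-diagonal block correlation matrix: ``within_r`` inside each lobe
    block, ``between_r`` across blocks, optional symmetric jitter followed by
    projection to the nearest positive-definite correlation matrix
    (eigenvalue clipping + diagonal rescale)."""
    if sum(lobe_sizes) != n_rois:
        raise SchemaError(f"lobe sizes {lobe_sizes} do not sum to n_rois={n_rois}")
    if not (abs(within_r) < 1 and abs(between_r) < 1 and within_r >= between_r):
        raise SchemaError("need |r| < 1 and within_r >= between_r")
    m = np.full((n_rois, n_rois), float(between_r))
    start = 0
    for size in lobe_sizes:
        m[start:start + size, start:start + size] = within_r
        start += size
    np.fill_diagonal(m, 1.0)
    if jitter > 0:
        rng = np.random.default_rng(seed)
        noise = rng.normal(0.0, jitter, size=(n_rois, n_rois))
        noise = (noise + noise.T) / 2.0
        np.fill_diagonal(noise, 0.0)
        m = m + noise
    if np.linalg.eigvalsh(m).min() <= 0:
        vals, vecs = np.linalg.eigh(m)
        m = (vecs * np.clip(vals, 1e-6, None)) @ vecs.T
        d = np.sqrt(np.diag(m))
        m = m / np.outer(d, d)
        m = (m + m.T) / 2.0
        np.fill_diagonal(m, 1.0)
    if np.linalg.eigvalsh(m).min() <= 0:
        raise GenerationError("block covariance not positive definite after projection")
    return StateSpec(name, m)


# ---------------------------------------------------------------------------
# run and cohort simulation
# ---------------------------------------------------------------------------

def simulate_run(states: list[StateSpec], switching: SwitchingSpec, t_points: int,
                 tr_seconds: float, seed: int, *, ar_coef: float = 0.0,
                 participant_id: str = "sim", session: str = "pre_op",
                 run_id: str = "run-1") -> tuple[RoiTimeSeries, SimulationGroundTruth]:
    """Draw one run: hidden Markov state path + state-conditional Gaussian draws.

    With ``ar_coef`` = a > 0, innovations are AR(1)-smoothed
    (x_t = a x_{t-1} + sqrt(1-a^2) e_t), preserving the stationary covariance.
    """
    ns = {s.n_rois for s in states}
    if len(ns) != 1:
        raise SchemaError(f"states disagree on ROI count: {sorted(ns)}")
    if len(states) != switching.n_states:
        raise SchemaError("number of states != switching matrix size")
    if t_points < 2:
        raise SchemaError("t_points must be >= 2")
    n = ns.pop()
    rng = np.random.default_rng(seed)
    k = len(states)
    labels = np.empty(t_points, dtype=np.int64)
    labels[0] = rng.choice(k, p=switching.initial_distribution)
    u = rng.random(t_points - 1)
    cum = np.cumsum(switching.transition_matrix, axis=1)
    for t in range(1, t_points):
        labels[t] = np.searchsorted(cum[labels[t - 1]], u[t - 1], side="right")
    chols = [np.linalg.cholesky(s.covariance) for s in states]
    z = rng.standard_normal((t_points, n))
    if ar_coef:
        a = float(ar_coef)
        if not (0 <= a < 1):
            raise SchemaError("ar_coef must lie in [0, 1)")
        scale = np.sqrt(1.0 - a * a)
        for t in range(1, t_points):
            z[t] = a * z[t - 1] + scale * z[t]
    data = np.empty((t_points, n))
    for s in range(k):
        mask = labels == s
        data[mask] = z[mask] @ chols[s].T
    roi_names = [f"roi{i + 1:03d}" for i in range(n)]
    run = RoiTimeSeries(data, roi_names, tr_seconds, participant_id, session, run_id)
    truth = SimulationGroundTruth(labels, switching.stationary_distribution(),
                                  switching.mean_sojourn_tr(), int(seed))
    return run, truth


def majority_window_labels(labels_per_tr: np.ndarray, length_tr: int,
                           step_tr: int = 1) -> np.ndarray:
    """Ground-truth label per window: majority of per-TR labels, ties going to
    the earlier (lower-index) state."""
    labels_per_tr = np.asarray(labels_per_tr)
    t = len(labels_per_tr)
    n_win = (t - length_tr) // step_tr + 1
    out = np.empty(n_win, dtype=np.int64)
    for w in range(n_win):
        start = w * step_tr
        out[w] = np.bincount(labels_per_tr[start:start + length_tr]).argmax()
    return out


@dataclass
class ScenarioSpec:
    """One session condition: states, switching, and run layout."""

    states: list[StateSpec]
    switching: SwitchingSpec
    n_runs: int
    t_points: int
    tr_seconds: float
    ar_coef: float = 0.0


def _two_state_switching(occupancy_strong: float, sojourn_strong_tr: float) -> SwitchingSpec:
    """Two-state chain with the requested stationary occupancy of state 0 and
    mean sojourn of state 0; state 1's sojourn follows from the occupancy ratio."""
    s0 = float(sojourn_strong_tr)
    s1 = s0 * (1.0 - occupancy_strong) / occupancy_strong
    p = np.array([[1.0 - 1.0 / s0, 1.0 / s0], [1.0 / s1, 1.0 - 1.0 / s1]])
    return SwitchingSpec(p)


def paper_like_scenarios(n_rois: int = 24, n_lobes: int = 6, tr_seconds: float = 2.0,
                         ) -> tuple[ScenarioSpec, ScenarioSpec]:
    """Default pre/post study conditions.

    Pre-op: strong state (within/between lobe r = 0.75/0.134, mean r ~ 0.214)
    and sparse state (0.25/0.053, mean r ~ 0.079); occupancy 0.57/0.43 with
    mean sojourns 360/272 TR; 3 runs of 144 TR (~4.8 min at TR 2 s).
    Post-op: stimulation-like effect — absolute correlation drops of
    0.08 within / 0.06 between lobes for the strong state (-> 0.67/0.074) and
    0.05/0.02 for the sparse state (-> 0.20/0.033), occupancy shifted to
    0.16/0.84 with sojourns 50/262 TR; 3 runs of 300 TR (~10 min).
    """
    if n_rois % n_lobes:
        raise SchemaError("n_rois must be divisible by n_lobes")
    sizes = [n_rois // n_lobes] * n_lobes
    strong_pre = make_block_covariance(n_rois, sizes, 0.75, 0.134, name="strong")
    sparse_pre = make_block_covariance(n_rois, sizes, 0.25, 0.053, name="sparse")
    strong_post = make_block_covariance(n_rois, sizes, 0.67, 0.074, name="strong")
    sparse_post = make_block_covariance(n_rois, sizes, 0.20, 0.033, name="sparse")
    pre = ScenarioSpec([strong_pre, sparse_pre],
                       _two_state_switching(0.57, 360.0), n_runs=3,
                       t_points=144, tr_seconds=tr_seconds)
    post = ScenarioSpec([strong_post, sparse_post],
                        _two_state_switching(0.16, 50.0), n_runs=3,
                        t_points=300, tr_seconds=tr_seconds)
    return pre, post


def null_no_effect_scenarios(n_rois: int = 24, n_lobes: int = 6, tr_seconds: float = 2.0,
                             ) -> tuple[ScenarioSpec, ScenarioSpec]:
    """Null condition: post-op identical in law to pre-op (no planted effect)."""
    pre, _ = paper_like_scenarios(n_rois, n_lobes, tr_seconds)
    post = ScenarioSpec(pre.states, pre.switching, pre.n_runs, pre.t_points,
                        pre.tr_seconds, pre.ar_coef)
    return pre, post


def metric_recovery_scenario(n_rois: int = 24, n_lobes: int = 6,
                             tr_seconds: float = 2.0) -> ScenarioSpec:
    """Calibration scenario for occupancy/dwell estimation: two maximally
    separated states (within-lobe r 0.9 vs uncorrelated) switching slowly
    (mean sojourn 200 TR each, stationary occupancy 0.5/0.5) over long runs,
    so window labelling is essentially noiseless and the state metrics can be
    compared against the chain's analytic values."""
    sizes = [n_rois // n_lobes] * n_lobes
    strong = make_block_covariance(n_rois, sizes, 0.9, 0.0, name="strong")
    sparse = make_block_covariance(n_rois, sizes, 0.0, 0.0, name="sparse")
    sw = SwitchingSpec(np.array([[0.995, 0.005], [0.005, 0.995]]))
    return ScenarioSpec([strong, sparse], sw, n_runs=4, t_points=60_000,
                        tr_seconds=tr_seconds)


SCENARIOS = {"paper_like": paper_like_scenarios, "null_no_effect": null_no_effect_scenarios}


@dataclass
class CohortSim:
    """In-memory cohort: runs, manifest, per-run ground truth keyed by run."""

    runs: list[RoiTimeSeries]
    manifest: RunManifest
    ground_truth: dict[tuple[str, str, str], SimulationGroundTruth]
    seed: int


def simulate_cohort(n_participants: int, pre_spec: ScenarioSpec, post_spec: ScenarioSpec,
                    seed: int, out_dir: str | Path | None = None,
                    scale_overrides: dict | None = None) -> CohortSim:
    """Simulate a pre/post cohort; optionally write per-run CSVs, a manifest
    and a ground-truth JSON under ``out_dir``.

    ``scale_overrides`` may shrink the scenarios' run layout
    (keys n_runs_pre/n_runs_post/t_pre/t_post) without touching the planted law.
    """
    ov = scale_overrides or {}
    layouts = {
        "pre_op": (pre_spec, ov.get("n_runs_pre", pre_spec.n_runs), ov.get("t_pre", pre_spec.t_points)),
        "post_op": (post_spec, ov.get("n_runs_post", post_spec.n_runs), ov.get("t_post", post_spec.t_points)),
    }
    ss = np.random.SeedSequence(seed)
    runs: list[RoiTimeSeries] = []
    entries: list[ManifestEntry] = []
    truths: dict[tuple[str, str, str], SimulationGroundTruth] = {}
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    for p in range(n_participants):
        pid = f"sub-{p + 1:03d}"
        for session, (spec, n_runs, t_points) in layouts.items():
            for r in range(n_runs):
                rid = f"run-{r + 1}"
                child = int(ss.spawn(1)[0].generate_state(1, dtype=np.uint32)[0]) % (2**31)
                run, truth = simulate_run(spec.states, spec.switching, t_points,
                                          spec.tr_seconds, child, ar_coef=spec.ar_coef,
                                          participant_id=pid, session=session, run_id=rid)
                runs.append(run)
                truths[run.key] = truth
                fname = f"{pid}_{session}_{rid}.csv"
                path = str(out / fname) if out is not None else fname
                entries.append(ManifestEntry(pid, session, rid, spec.tr_seconds, path))
                if out is not None:
                    pd.DataFrame(run.data, columns=run.roi_names).to_csv(out / fname, index=False)
    manifest = RunManifest(entries)
    if out is not None:
        pd.DataFrame([e.__dict__ for e in entries]).to_csv(out / "manifest.csv", index=False)
        write_report({"seed": seed, "runs": {
            "|".join(k): {"state_labels_per_tr": v.state_labels_per_tr,
                          "true_occupancy": v.true_occupancy,
                          "true_mean_sojourn_tr": v.true_mean_sojourn_tr,
                          "seed": v.seed} for k, v in truths.items()}},
            out / "ground_truth.json")
    return CohortSim(runs, manifest, truths, seed)


def cohort_lobe_map(n_rois: int = 24, n_lobes: int = 6) -> LobeMap:
    """Lobe map matching the simulated block structure (six synthetic lobes)."""
    lobes = ["frontal", "occipital", "parietal", "subcortical", "temporal", "cerebellum"][:n_lobes]
    per = n_rois // n_lobes
    mapping = {f"roi{i + 1:03d}": lobes[min(i // per, n_lobes - 1)] for i in range(n_rois)}
    return LobeMap(mapping, lobes)
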