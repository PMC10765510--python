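# dfcstates

Dynamic functional-connectivity (dFC) state analysis for parcellated fMRI
time series: sliding-window Pearson connectivity, cluster-quality-guided
K-means identification of recurring connectivity states, state metrics
(strength, occupancy rate, dwell time, transition rate), graph indicators of
binarized networks — static and per-window ("dynamic graph") — and
nonparametric pre/post comparison of everything, as used to study how
intracranial electrical stimulation reshapes brain networks in refractory
epilepsy (pre-implantation vs post-implantation resting-state sessions).

The package is built for two audiences: analysts with their own parcellated
time series (delimited text, one column per ROI, plus a run manifest with
participant, session `pre_op`/`post_op`, run id and TR), and method
developers, for whom a synthetic Markov-switching generator plants known
state structure — two lobe-block covariance regimes, a strongly and a
sparsely connected one, with a configurable "stimulation" effect — so every
stage can be validated against ground truth without any imaging data.

## Model summary

Windows of length *L* seconds (whole TRs, boxcar, step *s* TR) yield Pearson
matrices whose upper triangles are pooled across all participants and
sessions and clustered by Euclidean K-means (random data-point
initialisation, best of 10 restarts). With states ordered by centroid
strength (mean upper-triangle r), per participant-session metrics are

- occupancy = windows in state / total windows,
- dwell = mean maximal same-state run length × *s* × TR (seconds),
- transitions/min = label changes / windowed minutes,
- strength = mean r over member windows.

Cluster quality across parameter grids uses inertia, silhouette
(s_i = (b_i − a_i)/max(a_i, b_i)), Calinski–Harabasz and Davies–Bouldin.
Binarized networks (proportional density, default 0.15, or absolute r
threshold) are summarised by clustering coefficient, max k-core, modularity
(greedy CNM partition), degree assortativity, global and local efficiency.
Pre/post contrasts use the two-sided Mann–Whitney U test (exhaustive exact
enumeration for n₁+n₂ ≤ 12, tie-corrected normal approximation otherwise),
with Shapiro–Wilk/Levene preconditions reported; indicator traces get
ADF+KPSS stationarity verdicts and FFT periodicity reports. Details and
rationale: `docs/methods.md`.

## Worked example

```python
from dfcstates import paper_like_scenarios, run_state_pipeline, simulate_cohort

pre, post = paper_like_scenarios()          # planted pre/post study conditions
sim = simulate_cohort(6, pre, post, seed=3)
res = run_state_pipeline(sim.runs, window_seconds=60, step_tr=1, k=2,
                         restarts=10, seed=3)
print(res.model.centroid_strengths().round(3))
print(res.metrics.groupby(["session", "state"])[
    ["occupancy_rate", "dwell_time_seconds"]].mean().round(3))
```

prints

```
[0.194 0.059]
               occupancy_rate  dwell_time_seconds
session state
post_op 0               0.088              67.171
        1               0.912             365.560
pre_op  0               0.481             204.933
        1               0.519             198.333
```

Two states are found: state 1 (index 0) is the strongly connected regime
(mean centroid r 0.194) and state 2 the sparse one (0.059). After the
simulated stimulation the strong state loses occupancy (0.48 → 0.09) and
dwell time (205 s → 67 s) while the sparse state gains both — the planted
effect, recovered end to end. `examples/` contains one short script per
capability (simulation, state identification, quality sweeps, graph
indicators, dynamic-graph time-series analysis, lobe summaries), and the
`dfcstates` command line exposes the same pipeline as subcommands
(`simulate`, `dfc`, `sweep`, `states`, `graphs`, `stats`, `run-all`).

An editable AAL-116 → six-lobe assignment table ships with the package
(`dfcstates.default_lobe_map()`) for aggregating ROI-level centroids to
lobe-to-lobe mean connectivity.

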