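# Methods

## The analysis

`dfcstates` implements a state-based dynamic functional connectivity (dFC)
analysis for parcellated fMRI time series, together with graph-theoretic
summaries of the binarized networks and a nonparametric pre/post comparison
layer. The pipeline is:

1. **Windowed connectivity.** For each run (a T x N matrix of ROI signals with
   repetition time TR), the static FC matrix is the Pearson correlation over
   the whole run; the dFC series is the sequence of Pearson matrices over
   boxcar windows of fixed length (given in seconds, converted to whole TRs
   with ties rounding up) advanced by a whole-TR step. Windows use 0-based,
   half-open coordinates and never cross run boundaries. No Fisher
   z-transform, tapering or within-window detrending is applied: extras would
   move the cluster centroids.
2. **State identification.** The upper triangles of all windows of all
   participants and both sessions are pooled and clustered by a single
   Euclidean K-means (Lloyd iterations; centroids initialised uniformly at
   random from the data points; best inertia over `restarts` runs, default
   10; iteration stops when assignments are unchanged or after 300 rounds;
   nearest-centroid ties break toward the lower state index; an emptied
   cluster is reseeded deterministically with the worst-fit sample). States
   are reported in descending order of centroid strength — the mean
   upper-triangle r — so "state 1" is always the strongly connected state.
3. **Cluster quality.** Window length, step and k are selected by sweeping a
   grid and reporting four criteria per setting: inertia (for the elbow),
   mean silhouette s_i = (b_i - a_i)/max(a_i, b_i) with Euclidean
   dissimilarity, Calinski-Harabasz
   [Σ_k n_k‖z_k - z‖² / (K-1)] / [Σ_i‖x_i - z_{k(i)}‖² / (n-K)],
   and Davies-Bouldin (1/K) Σ_i max_{j≠i} (s_i + s_j)/d_ij with s_i the mean
   member-centroid distance. All three are implemented in closed form in this
   package and verified against brute-force evaluation to 1e-10 (scikit-learn's
   equivalents serve as an additional cross-check in the tests; its
   Davies-Bouldin uses the expanded dot-product identity and agrees only to
   ~1e-8, so the brute-force oracle is the reference). For very large window
   pools the silhouette (O(n²) pairwise distances) may be evaluated on a
   seeded subsample; inertia, CH and DB are always exact.
4. **State metrics.** Per participant and session: occupancy (windows in
   state / total windows), dwell time (mean length of maximal same-state
   window runs x step x TR, in seconds; runs from different acquisitions are
   never concatenated; an unvisited state yields a missing value, not zero),
   transition rate (label changes per minute of windowed time), and strength.
   Strength per participant-session is the mean r over that cell's member
   windows, so it can differ between sessions under the shared centroids;
   the pooled centroid strengths are reported separately on the state model.
5. **Graph indicators.** FC matrices are binarized either by proportional
   density (keep the top share of edges by r, default 0.15, ties resolved
   lexicographically; negative correlations excluded by default) or by an
   absolute cutoff (keep r > value). Six indicators are computed with
   networkx: mean nodal clustering coefficient, maximum k-core number,
   modularity of a greedy (CNM) modularity-maximising partition, degree
   assortativity (missing when undefined, e.g. regular graphs), global
   efficiency (unreachable pairs contribute 0) and local efficiency (mean
   global efficiency of open neighbourhood subgraphs). Applied per dFC
   window this gives temporal indicator traces ("dynamic graph" analysis).
6. **Statistics.** Group comparisons use the two-sided Mann-Whitney U test:
   exact by exhaustive enumeration over rank arrangements for n1+n2 ≤ 12
   (midranks handle ties), otherwise the tie-corrected normal approximation
   with continuity correction. The reported statistic is the standardised U
   of the pre-op sample (positive = larger before stimulation); `direction`
   is `no_change` whenever p ≥ alpha (default 0.05). Shapiro-Wilk and
   median-centred Levene precondition tests are attached for reference.
   P-values are uncorrected by default, matching common practice of testing
   each metric at alpha = 0.05; Benjamini-Hochberg correction and a paired
   Wilcoxon variant are available. Indicator traces additionally get an
   ADF (constant regression, AIC lag selection) + KPSS (level, Hobijn
   data-dependent lag) stationarity verdict and an FFT periodicity report
   (linear detrend; dominant frequency in cycles/window; peak-to-median
   power ratio, flagged periodic above a configurable cutoff, default 10).

## The synthetic generator

There is no bundled brain data; every analysis stage is exercised against a
generator that plants exactly the structure the pipeline assumes. Hidden
states follow a first-order Markov chain per TR; given the state, each time
point is an independent draw from a zero-mean multivariate normal whose
correlation matrix has lobe-block structure (within-lobe r ≥ between-lobe r).
An optional AR(1) coefficient adds temporal smoothness without changing the
stationary covariance. Ground truth accompanies every run: the per-TR label
path, the chain's stationary occupancy (left unit eigenvector) and its mean
sojourn 1/(1 - p_kk); window-level truth is defined by majority vote of the
per-TR labels (ties to the lower state index).

### Default study conditions (`paper_like`)

24 ROIs in six lobes of four, TR 2 s (TR is always carried explicitly in
manifests and never inferred). Pre-op: a strong state (within/between lobe
r = 0.75/0.134, centroid mean r ≈ 0.214) and a sparse state (0.25/0.053,
mean r ≈ 0.079); stationary occupancy 0.57/0.43 with mean sojourns 360/272 TR;
three runs of 144 TR (~4.8 min). Post-op: absolute correlation drops of 0.08
within / 0.06 between lobes for the strong state and 0.05/0.02 for the
sparse state; occupancy 0.16/0.84 with sojourns 50/262 TR; three runs of
300 TR (~10 min).

Why these numbers: occupancies, centroid strengths and the magnitude of the
strong-state connectivity drop are the quantities the reference es-fMRI
analyses report, and they are planted as stated. The remaining freedom —
block contrast and sojourn scale — is set so that the planted structure is
*recoverable* at this problem size: windowed correlations at 30 samples per
window carry entry-correlated noise whose projection on the state-separation
axis has a standard deviation near 0.7, and windows straddling a state
transition are intrinsically ambiguous, so sojourns are kept well above the
window length and the within-lobe contrast well above the noise scale.
Published dwell-time and transition-rate values are not jointly consistent
with any per-TR two-state chain once window-majority smoothing is accounted
for (a 30-TR window absorbs sub-window sojourns and inflates measured dwell),
so dwell is matched in direction, not magnitude, and the transition-rate
contrast is not planted at all. Short pre-op runs also censor long sojourns,
which biases measured dwell downward — another reason dwell magnitudes are
not read literally anywhere in the tests.

`null_no_effect` applies the pre-op law to both sessions. The type-I
calibration uses a desk-scale null variant with faster switching (sojourns
20/15 TR) so that per-participant occupancies vary continuously rather than
sitting at 0 or 1; with near-constant metrics the Mann-Whitney p collapses
to 1 and calibration would be untestable.

`metric_recovery_scenario` is the estimator-calibration condition: two
maximally separated states (within-lobe r 0.9 vs uncorrelated), symmetric
slow switching (sojourn 200 TR), four runs of 60,000 TR. In this regime
window labelling is essentially noiseless, which is the point: measured
occupancy and dwell can then be compared against the chain's analytic values
without conflating estimator bias with label noise. Two discretization
effects remain and bound what "recovery" can mean: label runs are chopped by
residual boundary jitter (biasing dwell down) and sojourns shorter than half
a window are absorbed by the majority rule (biasing dwell up, by roughly the
probability of a sub-half-window sojourn). At these settings both effects
stay within a few percent.

### What the generator does not emulate

No hemodynamic response convolution, scanner noise spectra, motion artifacts,
physiological confounds, stimulation block timing or inter-subject anatomy.
Observations are conditionally i.i.d. by default. Passing tests therefore
show that the pipeline's machinery recovers the statistical structure it is
designed to detect — not that real es-fMRI data satisfies that structure.

## Numerical choices

- Window length in seconds converts to TRs by rounding to nearest (ties up);
  lengths under 2 TR are rejected.
- Pearson matrices are symmetrised, clipped to [-1, 1], unit diagonal forced;
  zero-variance ROIs raise a named error rather than producing NaNs.
- Silhouette distances are computed from explicit differences (cdist), not
  the expanded dot-product identity, preserving ~1e-13 accuracy.
- Density binarization keeps exactly floor(density x N(N-1)/2) edges with
  deterministic lexicographic tie-breaks; with the negative-correlation
  floor enabled (default) fewer edges may survive.
- Degenerate cases are explicit: all-tied Mann-Whitney samples give p = 1 and
  `no_change`; a constant series is stationary-with-flag for ADF/KPSS and
  has no dominant FFT frequency; assortativity of a regular graph and
  modularity of an empty graph are missing values, not exceptions.
- All randomness flows through numpy Generators seeded from user-supplied
  integers; per-run seeds in cohorts derive from a SeedSequence spawn chain,
  so identical seeds give bit-identical cohorts.

## Known limitations

- The combined ADF+KPSS verdict can never classify a true unit-root series
  as "nonstationary" more than (1 - alpha) x KPSS-power of the time: ADF
  rejects its null (the unit root itself) at its nominal size, sending about
  alpha of replicates to the "conflicting" verdict. Measured on 400
  length-500 random walks the nonstationary rate is ~90%.
- The group tests treat pre-op and post-op as independent groups (as in the
  reference analysis pipeline) although the design is paired; a paired
  Wilcoxon option exists but is off by default.
- Dwell-time estimates from windowed labels are biased for sojourns near or
  below the window length (absorption and chopping, above); they are
  comparable across conditions analysed with the same window, but are not
  unbiased estimates of the underlying sojourn times.
- Greedy (CNM) modularity is a lower bound on the optimal partition's Q;
  tests verify it never exceeds the exhaustive-search optimum on small
  graphs, not that it attains it.
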