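import numpy as np
import pandas as pd
import pytest
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

import _oracles as oracle
from dfcstates import DegenerateInputError, MappingError
from dfcstates.clustering import (kmeans_states, lobe_difference, lobe_summary,
                                  pool_windows, quality_criteria, reports_to_frame,
                                  state_metrics, sweep)
from dfcstates.io import LobeMap
from dfcstates.simulate import ScenarioSpec, SwitchingSpec, make_block_covariance
from dfcstates.windows import FcMatrix, WindowSpec


class TestKmeans:
    def test_k1_centroid_is_mean_and_inertia_total_scatter(self, rng):
        x = rng.normal(size=(30, 6))
        m = kmeans_states(x, 1, restarts=3, seed=0)
        assert m.inertia == pytest.approx(((x - x.mean(0)) ** 2).sum())

    def test_two_separated_groups_recovered_exactly(self, rng):
        a = rng.normal(0, 0.1, size=(40, 5))
        b = rng.normal(8, 0.1, size=(40, 5))
        x = np.vstack([a, b])
        truth = np.r_[np.zeros(40), np.ones(40)]
        m = kmeans_states(x, 2, restarts=5, seed=1)
        assert adjusted_rand_score(truth, m.labels) == 1.0

    def test_k_equals_distinct_points_gives_zero_inertia(self):
        x = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        m = kmeans_states(x, 3, restarts=2, seed=0)
        assert m.inertia == pytest.approx(0.0)

    def test_fewer_distinct_windows_than_k(self):
        x = np.tile([[0.5, 0.5]], (6, 1))
        with pytest.raises(DegenerateInputError):
            kmeans_states(x, 2, restarts=1, seed=0)

    def test_states_ordered_by_descending_strength(self, rng):
        lo = rng.normal(0.05, 0.02, size=(30, 10))
        hi = rng.normal(0.5, 0.02, size=(30, 10))
        m = kmeans_states(np.vstack([lo, hi]), 2, restarts=5, seed=0)
        strengths = m.centroid_strengths()
        assert strengths[0] > strengths[1]
        assert np.all(m.labels[:30] == 1) and np.all(m.labels[30:] == 0)

    def test_best_of_restarts_not_worse_than_single_restart(self, rng):
        x = np.vstack([rng.normal(c, 0.5, size=(25, 4)) for c in (0, 3, 6)])
        multi = kmeans_states(x, 3, restarts=10, seed=7)
        single = kmeans_states(x, 3, restarts=1, seed=7)
        assert multi.inertia <= single.inertia + 1e-9

    def test_comparable_to_sklearn_solution(self, rng):
        x = np.vstack([rng.normal(c, 0.8, size=(40, 6)) for c in (0, 4)])
        mine = kmeans_states(x, 2, restarts=10, seed=0)
        sk = KMeans(2, init="random", n_init=10, random_state=0).fit(x)
        assert mine.inertia <= sk.inertia_ * 1.001


class TestQualityCriteria:
    def test_hand_worked_two_cluster_example(self):
        x = np.array([[0.0], [0.1], [10.0], [10.1]])
        labels = np.array([0, 0, 1, 1])
        rep = quality_criteria(x, labels)
        # per-sample silhouettes: points 0/3 -> (10.05-0.1)/10.05,
        # points 1/2 -> (9.95-0.1)/9.95; the report averages the four
        expected = np.mean([9.95 / 10.05, 9.85 / 9.95, 9.85 / 9.95, 9.95 / 10.05])
        assert rep.silhouette == pytest.approx(expected, abs=1e-12)
        assert rep.calinski_harabasz == pytest.approx(20_000.0, rel=1e-12)
        assert rep.davies_bouldin == pytest.approx(0.01, abs=1e-12)
        assert rep.inertia == pytest.approx(0.01, abs=1e-12)

    def test_matches_bruteforce_on_random_instances(self, rng):
        for _ in range(25):
            n = int(rng.integers(6, 30))
            x = rng.normal(size=(n, int(rng.integers(1, 5))))
            labels = rng.integers(0, int(rng.integers(2, 5)), size=n)
            if len(np.unique(labels)) < 2:
                continue
            rep = quality_criteria(x, labels)
            assert rep.silhouette == pytest.approx(oracle.silhouette_brute(x, labels), abs=1e-10)
            assert rep.calinski_harabasz == pytest.approx(
                oracle.calinski_harabasz_brute(x, labels), rel=1e-10)
            assert rep.davies_bouldin == pytest.approx(
                oracle.davies_bouldin_brute(x, labels), abs=1e-10)
            assert rep.inertia == pytest.approx(oracle.inertia_brute(x, labels), rel=1e-10)

    def test_all_singletons_rejected(self):
        x = np.array([[0.0], [1.0], [2.0]])
        with pytest.raises(DegenerateInputError):
            quality_criteria(x, np.array([0, 1, 2]))


def _mini_cohort(seed=3, occupancy=0.5, sojourn=20.0, t=150, n_part=4):
    from dfcstates.simulate import _two_state_switching, paper_like_scenarios, simulate_cohort
    pre0, _ = paper_like_scenarios(n_rois=8, n_lobes=2)
    sc = ScenarioSpec(pre0.states, _two_state_switching(occupancy, sojourn), 1, t, 2.0)
    return simulate_cohort(n_part, sc, sc, seed=seed)


class TestSweep:
    def test_single_value_grid_matches_direct_evaluation(self):
        sim = _mini_cohort()
        reps = sweep("k", [2], sim.runs, window_seconds=20, step_tr=2, restarts=3, seed=0)
        assert len(reps) == 1 and reps[0].error is None
        x, _, _ = pool_windows(sim.runs, WindowSpec(20, 2))
        model = kmeans_states(x, 2, 3, 0)
        direct = quality_criteria(x, model.labels)
        assert reps[0].silhouette == pytest.approx(direct.silhouette)
        assert reps[0].davies_bouldin == pytest.approx(direct.davies_bouldin)

    def test_planted_two_state_cohort_peaks_at_k2(self):
        sim = _mini_cohort(seed=5, occupancy=0.5, sojourn=40.0, t=200)
        reps = sweep("k", [2, 3, 4], sim.runs, window_seconds=40, step_tr=2,
                     restarts=5, seed=0)
        sils = [r.silhouette for r in reps]
        assert int(np.argmax(sils)) == 0

    def test_single_state_cohort_ch_decreases_with_k(self):
        from dfcstates.simulate import paper_like_scenarios, simulate_cohort
        pre0, _ = paper_like_scenarios(n_rois=8, n_lobes=2)
        sc = ScenarioSpec([pre0.states[0]], SwitchingSpec(np.array([[1.0]])), 1, 150, 2.0)
        drops = []
        for seed in (0, 1, 2):
            sim = simulate_cohort(3, sc, sc, seed=seed)
            reps = sweep("k", [2, 3], sim.runs, window_seconds=20, step_tr=2,
                         restarts=3, seed=seed)
            drops.append(reps[0].calinski_harabasz - reps[1].calinski_harabasz)
        assert np.mean(drops) > 0

    def test_invalid_grid_value_recorded_not_raised(self):
        sim = _mini_cohort()
        reps = sweep("window_seconds", [20.0, 1e6], sim.runs, step_tr=2, k=2,
                     restarts=2, seed=0)
        assert reps[0].error is None and reps[1].error
        frame = reports_to_frame(reps)
        assert list(frame["value"]) == [20.0, 1e6]

    def test_window_sweep_runs_over_grid(self):
        sim = _mini_cohort()
        reps = sweep("window_seconds", [20.0, 30.0, 40.0], sim.runs, step_tr=2, k=2,
                     restarts=2, seed=0)
        assert all(r.error is None for r in reps)


class TestStateMetrics:
    def _model_for(self, labels, k=2):
        from dfcstates.clustering import StateModel
        centers = np.linspace(0.5, 0.1, k)[:, None]  # descending strengths
        return StateModel(k, centers, np.asarray(labels), 0.0, 0, 1)

    def _prov(self, n, pid="p1", session="pre_op", run="run-1", tr=2.0, step=1):
        return pd.DataFrame({"participant_id": [pid] * n, "session": [session] * n,
                             "run_id": [run] * n, "window_index": range(n),
                             "tr_seconds": [tr] * n, "step_tr": [step] * n})

    def test_occupancy_from_label_counts(self):
        m = self._model_for([0, 0, 0, 1])
        out = state_metrics(m, self._prov(4))
        occ = out.set_index("state")["occupancy_rate"]
        assert occ[0] == pytest.approx(0.75) and occ[1] == pytest.approx(0.25)

    def test_dwell_and_transition_conventions(self):
        # labels 0,0,1,1,1,0 at step 1, TR 2 s: dwell(0)=mean(2,1)*2=3 s,
        # dwell(1)=6 s; 2 label changes over 12 s of windowed time -> 10/min
        m = self._model_for([0, 0, 1, 1, 1, 0])
        out = state_metrics(m, self._prov(6))
        row = out.set_index("state")
        assert row.loc[0, "dwell_time_seconds"] == pytest.approx(3.0)
        assert row.loc[1, "dwell_time_seconds"] == pytest.approx(6.0)
        assert row.loc[0, "transitions_per_minute"] == pytest.approx(10.0)

    def test_unvisited_state_missing_not_zero(self):
        # participant p1 never enters state 1; p2 does (keeping the fitted
        # model globally valid)
        m = self._model_for([0, 0, 0, 0, 1, 1])
        prov = pd.concat([self._prov(4), self._prov(2, pid="p2")], ignore_index=True)
        out = state_metrics(m, prov)
        p1 = out[out.participant_id == "p1"].set_index("state")
        assert p1.loc[0, "occupancy_rate"] == 1.0
        assert p1.loc[0, "transitions_per_minute"] == 0.0
        assert np.isnan(p1.loc[1, "dwell_time_seconds"])
        assert np.isnan(p1.loc[1, "strength"]) or p1.loc[1, "strength"] == 0.1
        assert p1.loc[1, "occupancy_rate"] == 0.0

    def test_runs_never_concatenated_for_dwell(self):
        # run-1 ends in state 0 and run-2 starts in state 0: the two visits
        # stay separate (dwell 4 s), they do not merge into one 8 s visit
        m = self._model_for([1, 0, 0, 0, 0, 1])
        prov = pd.concat([self._prov(3), self._prov(3, run="run-2")], ignore_index=True)
        out = state_metrics(m, prov).set_index("state")
        assert out.loc[0, "dwell_time_seconds"] == pytest.approx(4.0)

    def test_occupancies_sum_to_one_per_cell(self, tiny_cohort):
        from dfcstates.pipeline import run_state_pipeline
        res = run_state_pipeline(tiny_cohort.runs, 20, 2, 2, 3, seed=0)
        sums = res.metrics.groupby(["participant_id", "session"])["occupancy_rate"].sum()
        np.testing.assert_allclose(sums, 1.0, atol=1e-12)

    def test_label_permutation_permutes_metrics(self):
        labels = np.array([0, 0, 1, 1, 1, 0, 0, 1])
        m = self._model_for(labels)
        out = state_metrics(m, self._prov(8)).set_index("state")
        m2 = self._model_for(1 - labels)
        out2 = state_metrics(m2, self._prov(8)).set_index("state")
        for col in ("occupancy_rate", "dwell_time_seconds"):
            np.testing.assert_allclose(out.loc[[0, 1], col], out2.loc[[1, 0], col])

    def test_strength_uses_member_windows_when_features_given(self):
        m = self._model_for([0, 0, 1, 1])
        feats = np.array([[0.5], [0.7], [0.1], [0.3]])
        out = state_metrics(m, self._prov(4), feats).set_index("state")
        assert out.loc[0, "strength"] == pytest.approx(0.6)
        assert out.loc[1, "strength"] == pytest.approx(0.2)


class TestLobeSummary:
    def _lobe_map(self):
        return LobeMap({"a": "L1", "b": "L1", "c": "L2", "d": "L2"}, ["L1", "L2"])

    def test_constant_offdiagonal(self):
        m = np.full((4, 4), 0.3)
        np.fill_diagonal(m, 1.0)
        fc = FcMatrix(m, ["a", "b", "c", "d"])
        out = lobe_summary(fc, self._lobe_map())
        np.testing.assert_allclose(out["mean_r"], 0.3, atol=1e-12)

    def test_block_means_recovered_exactly(self):
        m = np.array([[1.0, 0.6, 0.2, 0.2],
                      [0.6, 1.0, 0.2, 0.2],
                      [0.2, 0.2, 1.0, 0.1],
                      [0.2, 0.2, 0.1, 1.0]])
        out = lobe_summary(FcMatrix(m, list("abcd")), self._lobe_map())
        vals = out.set_index(["lobe_i", "lobe_j"])["mean_r"]
        assert vals[("L1", "L1")] == pytest.approx(0.6)
        assert vals[("L1", "L2")] == pytest.approx(0.2)
        assert vals[("L2", "L2")] == pytest.approx(0.1)

    def test_self_difference_is_zero(self):
        m = np.full((4, 4), 0.3)
        np.fill_diagonal(m, 1.0)
        s = lobe_summary(FcMatrix(m, list("abcd")), self._lobe_map())
        diff = lobe_difference(s, s)
        np.testing.assert_allclose(diff["mean_r"], 0.0, atol=1e-15)

    def test_unmapped_roi_raises(self):
        fc = FcMatrix(np.eye(2), ["a", "zzz"])
        with pytest.raises(MappingError, match="zzz"):
            lobe_summary(fc, self._lobe_map())
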