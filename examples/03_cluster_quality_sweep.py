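"""Choose the number of states with the four cluster-quality criteria.

Inertia (elbow), silhouette, Calinski-Harabasz and Davies-Bouldin are
computed for each candidate k over the pooled dFC windows. On a two-state
cohort the silhouette peaks at k = 2 (higher is better; for Davies-Bouldin
lower is better).
"""

from dfcstates import paper_like_scenarios, simulate_cohort
from dfcstates.clustering import reports_to_frame, sweep

pre, post = paper_like_scenarios()
sim = simulate_cohort(4, pre, post, seed=5)

reports = sweep("k", [2, 3, 4, 5, 6], sim.runs, window_seconds=60, step_tr=1,
                restarts=5, seed=5, silhouette_sample_size=3000)
frame = reports_to_frame(reports)
print(frame[["value", "inertia", "silhouette", "calinski_harabasz",
             "davies_bouldin"]].round(4).to_string(index=False))
best = frame.loc[frame["silhouette"].idxmax(), "value"]
print(f"\nsilhouette selects k = {int(best)}")
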