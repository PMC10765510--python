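import numpy as np
import pytest

from dfcstates.simulate import (ScenarioSpec, _two_state_switching, paper_like_scenarios,
                                simulate_cohort)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small but structured cohort: 4 participants, one short run per session,
    8 ROIs in 2 lobes, fast switching. Used wherever a realistic-but-cheap
    end-to-end input is needed."""
    pre0, _ = paper_like_scenarios(n_rois=8, n_lobes=2)
    pre = ScenarioSpec(pre0.states, _two_state_switching(0.57, 25.0), n_runs=1,
                       t_points=150, tr_seconds=2.0)
    post = ScenarioSpec(pre0.states, _two_state_switching(0.30, 15.0), n_runs=1,
                        t_points=150, tr_seconds=2.0)
    return simulate_cohort(4, pre, post, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
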