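import numpy as np
import pytest

from polywhorl.simulator import SimParams, run_simulation


@pytest.fixture(scope="session")
def simulated_runs():
    """The study conditions of the simulator: circumferences 54/72/90 in
    a 3:4:5 ratio, three seeded replicates each, calibrated defaults.

    Returns {(W, seed): (state, arrangement)}.  Session-scoped because the
    nine runs take ~40 s and several tests interrogate them.
    """
    runs = {}
    for w in (54, 72, 90):
        for seed in (1, 2, 3):
            params = SimParams(W=w, seed=seed)
            runs[(w, seed)] = run_simulation(params)
    return runs


@pytest.fixture
def rng():
    return np.random.default_rng(20230922)
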