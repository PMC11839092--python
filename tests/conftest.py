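import pytest

import speechtrf as st
from speechtrf.stats import AdjacencyGraph

#: gains chosen so the clean EEG is noise-free and purely linear
NOISEFREE_PARAMS = {"NR_on": (1.0, 0.5, 0.0), "NR_off": (0.7, 0.7, 0.0)}

#: boosting settings used for kernel-recovery checks: wider basis and finer
#: steps than the 50 ms default, which recovers shapes but not fine structure
RECOVERY_BOOST = st.BoostConfig(basis_width_ms=100.0, step_fraction=0.002,
                                max_iters=5000, patience=3)


@pytest.fixture(scope="session")
def small_config():
    return st.SimulationConfig(n_channels=4,
                               condition_params=dict(NOISEFREE_PARAMS))


@pytest.fixture(scope="session")
def ground_truth(small_config):
    return st.gen_ground_truth_trf(small_config, seed=7)


@pytest.fixture(scope="session")
def noisefree_trial(small_config, ground_truth):
    return st.simulate_trial(small_config, ground_truth, seed=11)


@pytest.fixture(scope="session")
def chain_adjacency():
    """8 channels in a line: c0-c1-...-c7."""
    labels = tuple(f"c{i}" for i in range(8))
    nbrs = {l: set() for l in labels}
    for i in range(len(labels) - 1):
        nbrs[labels[i]].add(labels[i + 1])
        nbrs[labels[i + 1]].add(labels[i])
    return AdjacencyGraph.from_sets(nbrs)
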