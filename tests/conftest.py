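import numpy as np
import pytest

import trustgames as tg


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_experiment_frame():
    """A small simulated dataset (2 conditions x 6 runs) shared by tests."""
    cfg = tg.ExperimentConfig(n_runs=6, master_seed=7)
    logs = tg.run_experiment(cfg, [tg.get_condition(2), tg.get_condition(13)])
    return tg.runs_to_frame(logs)
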