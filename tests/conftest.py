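import numpy as np
import pytest

from doublestep.gru import TrainConfig
from doublestep.simulate import SimParams, make_target_layout, simulate_session


@pytest.fixture(scope="session")
def layout():
    return make_target_layout()


@pytest.fixture(scope="session")
def session_exp1():
    """Default experiment-1 session (120 trials), shared across tests."""
    return simulate_session(SimParams.for_experiment(1, rng_seed=11), experiment=1)


@pytest.fixture(scope="session")
def session_exp2():
    return simulate_session(SimParams.for_experiment(2, rng_seed=22), experiment=2)


@pytest.fixture(scope="session")
def noise_free_params():
    return SimParams.for_experiment(1, position_noise_sd_cm=0.0, endpoint_sd_cm=0.0,
                                    rng_seed=5)


@pytest.fixture()
def tiny_train_config():
    """Small GRU settings for fast unit tests (not the analysis defaults)."""
    return TrainConfig(hidden_units=16, max_epochs=40, patience=8, seed=0)
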