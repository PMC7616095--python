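import numpy as np
import pytest

from dopadist.task_synth import (
    DEFAULT_TEMPLATES,
    BehaviorParams,
    TaskConfig,
    generate_session_events,
    simulate_spike_train,
)


@pytest.fixture(scope="session")
def default_config():
    return TaskConfig(seed=11)


@pytest.fixture(scope="session")
def session_events(default_config):
    rng = np.random.default_rng(11)
    return generate_session_events(default_config, rng=rng)


@pytest.fixture(scope="session")
def short_events():
    cfg = TaskConfig(n_trials=40, seed=23)
    return generate_session_events(cfg, rng=np.random.default_rng(23))


@pytest.fixture(scope="session")
def dls_train(session_events):
    rng = np.random.default_rng(7)
    return simulate_spike_train(DEFAULT_TEMPLATES["DLS"], session_events, rng,
                                unit_id="dls_demo")
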