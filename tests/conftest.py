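import numpy as np
import pytest

from vibroreach.config import ObserverParams, StudyConfig, TaskConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_task():
    """A desk-scale task: 4 blocks of 32 trials, coarse 5 ms sampling."""
    return TaskConfig(blocks_session1=2, blocks_session2=2, sample_dt_ms=5.0)


@pytest.fixture
def tiny_study(tiny_task):
    return StudyConfig(task=tiny_task, n_participants=3,
                       observer=ObserverParams(), seed=99)
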