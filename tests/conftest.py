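import numpy as np
import pytest

from empathkit.config import study1_config, study2_config


@pytest.fixture
def tiny_study1():
    """Smallest sensible picture-task config."""
    return study1_config(n_participants_per_group=3, n_trials_per_cell=6, seed=7)


@pytest.fixture
def tiny_study2():
    """Smallest sensible narrative-task config."""
    return study2_config(n_participants_per_group=3, n_trials_per_cell=2, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
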