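import logging

import numpy as np
import pytest

from lpsnet import SimConfig, make_leadfield

logging.getLogger("lpsnet").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def leadfield64():
    return make_leadfield(64, 84, spread=0.25, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def tiny_config():
    """Two-condition study small enough for per-test simulation."""
    return SimConfig(
        n_subjects=2, n_trials=8, n_channels=32, conditions=("WE-IL", "WE-IT"), seed=7
    )

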