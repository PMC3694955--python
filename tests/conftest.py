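import numpy as np
import pytest
from hypothesis import settings

import retinotopy as rt

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def matched():
    """Matched gradients/countergradients: closed-form map is the identity."""
    return rt.matched_gradient_set(1.0, 2.0)


@pytest.fixture(scope="session")
def mismatched():
    """Half-height countergradients: rostrally biased optimal map."""
    return rt.build_gradient_set(1.0, 2.0, 0.5, 2.0, 1.0, 2.0, 0.5, 2.0)


@pytest.fixture
def tiny_config():
    """Small, fast simulation configuration."""
    return rt.SimConfig(n_rgc=24, n_sc=30, terminals_per_axon=4,
                        mu=2.0, n_steps=30_000, seed=7)


def small_state(n_rgc=3, n_sc=5, counts=None):
    """Hand-built simulator state for move/compensation unit tests."""
    if counts is None:
        counts = np.zeros((n_rgc, n_sc), dtype=np.int64)
        counts[:, 0] = 4
    counts = np.asarray(counts, dtype=np.int64)
    return rt.SimState(counts=counts,
                       compensation=np.zeros(counts.shape[1]),
                       density=counts.sum(axis=0))
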