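import numpy as np
import pytest

from ptychocg import SimulationSpec, make_dataset


def random_instance(rng, H=8, W=8, S=4, n=5):
    """Small random geometry + complex object for operator tests."""
    obj = rng.standard_normal((H, W)) + 1j * rng.standard_normal((H, W))
    probe = rng.standard_normal((S, S)) + 1j * rng.standard_normal((S, S))
    pos = np.stack(
        [
            rng.integers(0, H - S + 1, size=n),
            rng.integers(0, W - S + 1, size=n),
        ],
        axis=1,
    )
    return obj, probe, pos


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_dataset():
    """96x96 star dataset with a 32x32 disk probe; noise-free, ~81 patterns."""
    spec = SimulationSpec(H=96, W=96, S=32, step=8, jitter=2, seed=5, n_spokes=8)
    return make_dataset(spec)


@pytest.fixture(scope="session")
def small_star_dataset():
    """128x128 star dataset used by the solver-level tests."""
    spec = SimulationSpec(H=128, W=128, S=32, step=8, jitter=2, seed=7, n_spokes=12)
    return make_dataset(spec)
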