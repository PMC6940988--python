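import numpy as np
import pytest

from tactoid import build_nanoplatelet
from tactoid.state import SystemState


@pytest.fixture(scope="session")
def default_platelet():
    return build_nanoplatelet()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_state(positions, charges=None, diameters=None, box_length=20.0, **kw):
    """Minimal ad-hoc state for force/observable tests."""
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    return SystemState(
        positions=positions,
        charges=np.zeros(n) if charges is None else np.asarray(charges, float),
        diameters=np.full(n, 0.4) if diameters is None else np.asarray(diameters, float),
        species=np.full(n, 2),
        molecule=np.arange(n),
        box_length=box_length,
        **kw,
    )


@pytest.fixture()
def make_state_factory():
    return make_state
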