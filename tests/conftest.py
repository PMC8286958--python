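import numpy as np
import pytest

from carmpose.phantoms import PhantomSpec, make_phantom
from carmpose.projector import CArmConfig


@pytest.fixture(scope="session")
def desk_spec() -> PhantomSpec:
    """Desk-scale femur phantom spec used across tests."""
    return PhantomSpec(grid_shape=(64, 64, 64), spacing_mm=2.5)


@pytest.fixture(scope="session")
def desk_phantom(desk_spec):
    return make_phantom(desk_spec)


@pytest.fixture(scope="session")
def tiny_spec() -> PhantomSpec:
    """Very small grid for fast projection-heavy tests."""
    return PhantomSpec(grid_shape=(32, 32, 32), spacing_mm=5.0)


@pytest.fixture(scope="session")
def tiny_phantom(tiny_spec):
    return make_phantom(tiny_spec)


@pytest.fixture(scope="session")
def desk_carm() -> CArmConfig:
    return CArmConfig(sim_resolution=96)


@pytest.fixture(scope="session")
def small_carm() -> CArmConfig:
    return CArmConfig(sim_resolution=32)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
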