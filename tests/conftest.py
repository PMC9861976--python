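import numpy as np
import pytest

from octga.phantom import DeviceGeometry, make_geometry


@pytest.fixture(scope="session")
def spectralis() -> DeviceGeometry:
    return make_geometry("spectralis")


@pytest.fixture(scope="session")
def cirrus() -> DeviceGeometry:
    return make_geometry("cirrus")


@pytest.fixture
def small_geometry() -> DeviceGeometry:
    """Tiny cube for fast unit tests."""
    return DeviceGeometry(n_bscans=24, n_ascans=48, n_depth=40)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
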