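import numpy as np
import pytest

from chromadefocus import DisplayGeometry
from chromadefocus.renderer import condition_kernels, plate_scale


@pytest.fixture(scope="session")
def display():
    return DisplayGeometry()


@pytest.fixture(scope="session")
def scales(display):
    return plate_scale(display)


@pytest.fixture(scope="session")
def csm(display):
    """(plan, kernels) for the color-signed myopic condition."""
    return condition_kernels("csm", display)


@pytest.fixture(scope="session")
def csh(display):
    return condition_kernels("csh", display)


@pytest.fixture(scope="session")
def reference(display):
    return condition_kernels("reference", display)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
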