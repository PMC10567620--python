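import numpy as np
import pytest

from tbpet import build_design, list_designs


def boxcar(x, width=5):
    """Centered moving average used to de-noise MC profiles for shape checks."""
    kernel = np.ones(width) / width
    return np.convolve(np.asarray(x, float), kernel, mode="same")


@pytest.fixture(scope="session")
def designs():
    """All bundled designs, built once."""
    return {name: build_design(name) for name in list_designs()}


@pytest.fixture(scope="session")
def full_bgo(designs):
    return designs["uexplorer_full_bgo_194"]


@pytest.fixture(scope="session")
def biograph(designs):
    return designs["biograph_vision"]
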