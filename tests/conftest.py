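import numpy as np
import pytest

from pcdsim import fixtures, spectra
from pcdsim.detector import detector_preset
from pcdsim.materials import get_material


@pytest.fixture(scope="session")
def rqa9():
    return spectra.rqa9_spectrum()


@pytest.fixture(scope="session")
def idcd():
    return detector_preset("iDCD-CZT")


@pytest.fixture(scope="session")
def iicd():
    return detector_preset("iICD-LaBr3")


@pytest.fixture(scope="session")
def ideal():
    return fixtures.ideal_detector()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def water():
    return get_material("water")


@pytest.fixture(scope="session")
def aluminum():
    return get_material("aluminum")
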