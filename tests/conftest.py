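import numpy as np
import pytest

from xecest.synthetic_data import gen_zspectrum, table1_presets
from xecest.zspec_model import AcquisitionParams


@pytest.fixture(scope="session")
def presets():
    return table1_presets()


@pytest.fixture(scope="session")
def acq():
    return AcquisitionParams()


@pytest.fixture(scope="session")
def apo_zspec(presets, acq):
    """Noiseless apo z-spectrum on the standard acquisition grid."""
    return gen_zspectrum(presets["apo"], acq)


@pytest.fixture(scope="session")
def npy_zspec(presets, acq):
    """Noiseless ligand-bound z-spectrum on the standard grid."""
    return gen_zspectrum(presets["npy"], acq)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
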