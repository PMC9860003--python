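import numpy as np
import pytest
from hypothesis import settings

from pcctmd.materials import get_material
from pcctmd.projection import Geometry
from pcctmd.spectrum import CHANNEL_PRESETS, DetectorResponse, source_spectrum

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")

# quiet expected overflow/underflow in the guarded spectral exponentials
np.seterr(over="ignore", under="ignore", invalid="ignore")

#: reduced scan profile used throughout the unit tests: quarter-resolution
#: grid, half detector sampling — enough for sub-percent FBP accuracy
TINY = dict(n_pixels=64, pixel_mm=4.0, n_cells=216, cell_pitch_mm=4.096,
            n_views=180)


@pytest.fixture(scope="session")
def tiny_geometry():
    return Geometry(n_cells=TINY["n_cells"], cell_pitch=TINY["cell_pitch_mm"],
                    n_views=TINY["n_views"])


@pytest.fixture(scope="session")
def spectrum_1e6():
    return source_spectrum(fluence_scale=1e6)


@pytest.fixture(scope="session")
def ideal_response():
    return DetectorResponse("ideal")


@pytest.fixture(scope="session")
def realistic_response():
    return DetectorResponse("realistic")


@pytest.fixture(scope="session")
def basis_2md():
    return (get_material("soft_tissue"), get_material("cortical_bone"))


@pytest.fixture(scope="session")
def channels_2md():
    return CHANNEL_PRESETS[2]
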