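import numpy as np
import pytest

from thermoflim.synthetic import SceneConfig, TruthCalibration, simulate_flim_scene


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def truth_calibration():
    return TruthCalibration()


@pytest.fixture(scope="session")
def two_cell_scene(truth_calibration):
    """A small scene with two cells at distinct temperatures, high photons."""
    return simulate_flim_scene(
        SceneConfig(
            shape=(16, 16),
            cell_temperatures=[28.0, 40.0],
            photons_per_pixel=5000.0,
            seed=42,
        ),
        calib=truth_calibration,
    )
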