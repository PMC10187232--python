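import numpy as np
import pytest

import spindlequant as sq


@pytest.fixture
def cal():
    return sq.Calibration(pixel_size_xy=0.1, z_step=0.25,
                          frame_interval=1.0, time_unit="min")


@pytest.fixture
def quiet_bipolar():
    """One noise-free bipolar cell with its manifest."""
    m = sq.BipolarManifest(seed=7, noise=sq.NoiseModel.off(),
                           background_level=0.0)
    return sq.simulate_bipolar_cell(m)


def uniform_image(value=7.0, shape=(64, 64), pixel_size=0.1):
    data = np.full((1,) + shape, float(value))
    return sq.CalibratedImage(data, ("channel", "y", "x"),
                              sq.Calibration(pixel_size_xy=pixel_size),
                              ["ch"])
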