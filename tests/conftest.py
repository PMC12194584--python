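import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

from acrcnr import SearchConfig
from acrcnr.synthetic import SyntheticPhantomConfig, generate_slice


@pytest.fixture(scope="session")
def default_cfg():
    return SearchConfig()


@pytest.fixture(scope="session")
def noiseless_cfg():
    return SyntheticPhantomConfig(noise_sd_hu=0.0, n_slices=1)


@pytest.fixture(scope="session")
def noiseless_slice(noiseless_cfg):
    """Noiseless default phantom: 200 mm body at 90 HU, +6 HU object at 134°."""
    return generate_slice(noiseless_cfg, 0)


@pytest.fixture(scope="session")
def noisy_slice():
    """Default study conditions: contrast 6 HU, noise SD 3 HU."""
    return generate_slice(SyntheticPhantomConfig(), 42)


@pytest.fixture()
def flat_image():
    """A 64x64 uniform 0 HU image at 1 mm spacing for hand-built ROI tests."""
    from acrcnr import image_from_array

    return image_from_array(np.zeros((64, 64)), (1.0, 1.0))
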