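import numpy as np
import pytest

from dropletquant.synthetic import CompositionModel, ImagingConfig

#: imaging settings with every noise source disabled
NOISELESS = dict(background=0.0, read_noise_sd=0.0, shot_noise=False)


@pytest.fixture
def noiseless_config():
    return ImagingConfig(psf_sigma_nm=150.0, **NOISELESS)


@pytest.fixture
def small_composition():
    """Small droplets suited to compact (few-hundred-pixel) test fields."""
    return CompositionModel(radius_log_median_nm=500.0, radius_log_sigma=0.3)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
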