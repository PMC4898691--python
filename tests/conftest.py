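import numpy as np
import pytest

from bbekit import synthetic_data as sd
from bbekit import activesite


@pytest.fixture(scope="session")
def default_basis():
    return sd.make_basis(sd.DEFAULT_BAND_MODELS, np.arange(300.0, 701.0, 1.0))


@pytest.fixture
def noiseless_config():
    return sd.GeneratorConfig(seed=0, noise_sd_AU=0.0)


@pytest.fixture
def noisy_config():
    return sd.GeneratorConfig(seed=0)


@pytest.fixture(scope="session")
def reference():
    return activesite.reference_record()
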