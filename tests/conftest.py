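import numpy as np
import pytest

import pepmc


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_landscape():
    """Deterministic (noise 0) additive landscape on a 3-mer / 4-letter space."""
    landscape = pepmc.generate_landscape(
        length=3, alphabet="AGRY", noise_sd=0.0, seed=11
    )
    return landscape


@pytest.fixture
def binding_config():
    return pepmc.DockingConfig(site_label=pepmc.SITE_BINDING)


@pytest.fixture
def control_config():
    return pepmc.DockingConfig(site_label=pepmc.SITE_CONTROL)
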