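import numpy as np
import pytest

from ringcorr import MaskedImage, SimulationConfig, synthetic_axon_mask


@pytest.fixture(scope="session")
def straight_band_mask():
    """50 px tall, 1000 px long straight horizontal band (10 um at 100 px/um)."""
    return np.ones((50, 1000), dtype=bool)


@pytest.fixture(scope="session")
def default_sim_cfg():
    return SimulationConfig()


@pytest.fixture()
def small_masked_image():
    """Tiny two-channel image with a full mask for plumbing tests."""
    rng = np.random.default_rng(0)
    ch1 = rng.random((20, 40))
    ch2 = rng.random((20, 40))
    return MaskedImage(
        channels=[ch1, ch2], mask=np.ones((20, 40), bool), pixels_per_um=100.0
    )


@pytest.fixture(scope="session")
def short_axon_mask():
    """Small synthetic axon for fast end-to-end tests."""
    return synthetic_axon_mask(length_um=10.0, seed=42)
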