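import numpy as np
import pytest

from pcnnseg import (ModelParams, estimate_stats, four_level_phantom,
                     spcnn_auto_params, two_band_phantom)


@pytest.fixture(scope="session")
def two_band():
    """Equal-area two-band phantom, levels 0.2 / 0.8."""
    return two_band_phantom(64, 64, (0.2, 0.8), seed=1)


@pytest.fixture(scope="session")
def four_level():
    """Canonical four-level recovery phantom (monotone bands)."""
    return four_level_phantom(seed=0)


@pytest.fixture(scope="session")
def random_stimulus():
    rng = np.random.default_rng(42)
    return rng.uniform(0.05, 1.0, size=(32, 32))


@pytest.fixture(scope="session")
def auto_params(random_stimulus) -> ModelParams:
    return spcnn_auto_params(estimate_stats(random_stimulus))
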