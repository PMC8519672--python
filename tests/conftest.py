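import numpy as np
import pytest

from liverseg import data_io, phantom, training


@pytest.fixture(scope="session")
def small_phantom():
    """A deterministic (8, 32, 32) phantom with foreground on every slice."""
    spec = phantom.PhantomSpec(shape=(8, 32, 32), radius_range=(0.25, 0.4),
                               noise_sd=15.0, seed=7)
    volume, mask = phantom.generate_phantom(spec)
    return spec, volume, mask


@pytest.fixture(scope="session")
def small_dataset(small_phantom):
    """Eight windowed slice triplets with center-slice masks."""
    _, volume, mask = small_phantom
    normed = data_io.window_normalize(data_io.CTVolume(volume))
    return training.triplet_dataset(normed, mask)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
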