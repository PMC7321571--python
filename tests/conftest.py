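import numpy as np
import pytest
from hypothesis import settings

import dvcstrain as ds

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def speckle():
    """Small noiseless two-region phantom with lacunae texture (96^3)."""
    spec = ds.PhantomSpec(
        shape=(96, 96, 96),
        lacunae_density_per_region=(25_000.0, 40_000.0),
        noise_sd=0.0,
        seed=7,
    )
    vol, labels = ds.generate_phantom(spec)
    return vol, labels


@pytest.fixture(scope="session")
def flat_slab():
    """Noiseless texture-free two-level slab with a flat interface (64^3)."""
    spec = ds.PhantomSpec(
        shape=(64, 64, 64),
        interface_roughness_amp=0.0,
        lacunae_density_per_region=(0.0, 0.0),
        noise_sd=0.0,
        seed=0,
    )
    vol, labels = ds.generate_phantom(spec)
    return vol, labels


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
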