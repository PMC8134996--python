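import numpy as np
import pytest

from woundmetrics.synthetic import PhantomParams, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_phantom():
    """One deterministic phantom with satellites, shared across tests."""
    return generate_phantom(PhantomParams(canvas=(128, 128), main_radius=30,
                                          satellite_count=2), seed=42)


def random_mask_pair(rng, shape=(32, 32)):
    """Two random blobby masks with a guaranteed nonempty reference."""
    while True:
        ref = rng.random(shape) < rng.uniform(0.2, 0.8)
        test = rng.random(shape) < rng.uniform(0.2, 0.8)
        if ref.sum() > 0:
            return ref, test
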