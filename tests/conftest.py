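import numpy as np
import pytest

from angioquant import (
    PentaflakeSpec,
    VesselPhantomSpec,
    generate_pentaflake,
    generate_vessel_phantom,
)


@pytest.fixture(scope="session")
def pentaflake_1024():
    """The full fifth-iteration pentaflake calibration raster."""
    return generate_pentaflake(PentaflakeSpec(iteration=5, raster_size=1024))


@pytest.fixture(scope="session")
def phantom_pair():
    """A default noisy vessel phantom with its ground-truth mask."""
    return generate_vessel_phantom(VesselPhantomSpec(seed=3))


@pytest.fixture(scope="session")
def easy_phantom_pair():
    """A noiseless high-contrast phantom (the easiest segmentation regime)."""
    spec = VesselPhantomSpec(seed=11, noise_sigma=0.0)
    return generate_vessel_phantom(spec)


def random_blob_mask(rng: np.random.Generator, shape=(40, 40), density=0.3) -> np.ndarray:
    return rng.random(shape) < density
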