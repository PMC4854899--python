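import numpy as np
import pytest

from atlasvol.image_io import LabelMap, VolumeImage
from atlasvol.synthetic import PhantomSpec, make_phantom_atlas


@pytest.fixture(scope="session")
def atlas():
    """Default synthetic atlas (64^3 at 0.16 mm): image, 39 labels, table."""
    return make_phantom_atlas(PhantomSpec())


@pytest.fixture(scope="session")
def small_atlas():
    """Coarse phantom for registration-speed-sensitive tests."""
    spec = PhantomSpec(dims=(32, 32, 32), spacing_mm=0.32,
                       brain_semiaxes_vox=(13.0, 11.0, 10.0),
                       ventricle_semiaxes_vox=(5.2, 3.5, 3.2),
                       min_structure_voxels=5)
    return make_phantom_atlas(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(20160504)


@pytest.fixture
def random_image(rng):
    data = rng.uniform(10, 100, size=(16, 16, 16))
    return VolumeImage(data, spacing=(0.16, 0.16, 0.16))


@pytest.fixture
def random_labels(rng):
    data = rng.integers(0, 40, size=(16, 16, 16))
    return LabelMap(data.astype(np.int32), spacing=(0.16, 0.16, 0.16))
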