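import numpy as np
import pytest
from hypothesis import settings

from btseg import phantoms

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def phantom96():
    """Canonical 96x96 clean phantom: (spec, image, tumour mask, regions)."""
    spec = phantoms.PhantomSpec(height=96, width=96, tumour_radius=10, seed=3)
    img, mask = phantoms.make_phantom(spec)
    regions = phantoms.make_region_map(spec)
    return spec, img, mask, regions


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
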