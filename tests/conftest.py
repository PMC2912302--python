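import numpy as np
import pytest

from somabda.phantoms import PhantomSpec, add_extensions, half_ellipsoid
from somabda.pipeline import PipelineConfig

# noiseless phantoms: no plane correction, no dish cut
PHANTOM_CFG = PipelineConfig(min_height=0.0, plane_correction=False)


@pytest.fixture(scope="session")
def hemisphere():
    """Default 30x30 hemisphere phantom (r_0 = 5, centre between lattice rows)."""
    return half_ellipsoid(PhantomSpec())


@pytest.fixture(scope="session")
def hemisphere_with_extensions():
    spec = PhantomSpec()
    return add_extensions(half_ellipsoid(spec), spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)
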