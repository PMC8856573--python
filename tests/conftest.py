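import numpy as np
import pytest

from dwisynth import PhantomSpec, default_config, generate_phantom, write_phantom

#: small, coarse phantom (32^3 at 4 mm) used by most tests; same geometry
#: regime as the default, an order of magnitude fewer voxels
SMALL_SPEC = PhantomSpec(shape=(32, 32, 32), voxel_size_mm=4.0)


@pytest.fixture(scope="session")
def cfg():
    return default_config()


@pytest.fixture(scope="session")
def small_phantom():
    return generate_phantom(SMALL_SPEC)


@pytest.fixture(scope="session")
def phantom_dir(tmp_path_factory, small_phantom):
    """Phantom written to disk in the file layout the pipeline consumes."""
    out = tmp_path_factory.mktemp("phantom")
    paths = write_phantom(small_phantom, out)
    return paths


@pytest.fixture()
def rng():
    return np.random.default_rng(20260923)
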