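import numpy as np
import pytest

from octreveng.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def small_spec():
    """Desk-scale phantom: small enough for fast tests, large enough for
    every geometric stage to be nontrivial."""
    return PhantomSpec(volume_shape=(64, 64, 8), n_druse_clusters=1,
                       n_foci=2, n_sdd=1, druse_radius_range=(24.0, 36.0),
                       focus_radius_range=(1.5, 2.5), conversion_margin=4,
                       seed=42)


@pytest.fixture(scope="session")
def small_case(small_spec):
    return generate_phantom(small_spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
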