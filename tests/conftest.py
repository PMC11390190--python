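import numpy as np
import pytest

from thyronet.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def nodule_phantom():
    """256x256 phantom with one nodule; session-scoped (pure function of spec)."""
    spec = PhantomSpec(height=256, width=256, n_nodules=1,
                       nodule_radius_range=(24, 40), nodule_contrast=0.5,
                       background_mean=140.0, seed=7)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def clean_background_phantom():
    """Nodule-free 256x256 phantom (pure speckle over a flat echo level)."""
    spec = PhantomSpec(height=256, width=256, n_nodules=0, seed=11)
    return generate_phantom(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
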