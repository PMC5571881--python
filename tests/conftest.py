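import numpy as np
import pytest

from ironmark import PhantomSpec
from ironmark.registration import RigidTransform


@pytest.fixture(scope="session")
def noiseless_still_spec():
    """Phantom with no noise, no motion, no lesion: the identity case."""
    return PhantomSpec(
        noise_sigma=0.0,
        enhancement_lesions=[],
        inter_visit_motion=RigidTransform(),
        seed=0,
    )


@pytest.fixture(scope="session")
def default_lesion():
    return PhantomSpec().enhancement_lesions


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
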