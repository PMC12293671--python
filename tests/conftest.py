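import numpy as np
import pytest

from octamorph.synthetic import VascularPhantomSpec, generate_vascular_phantom


@pytest.fixture(scope="session")
def phantom():
    """One default-condition phantom shared across tests (seed 1)."""
    return generate_vascular_phantom(VascularPhantomSpec(seed=1))


@pytest.fixture(scope="session")
def phantom_bank():
    """Small bank of phantoms at the default study conditions (seeds 0-7)."""
    return [generate_vascular_phantom(VascularPhantomSpec(seed=s)) for s in range(8)]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
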