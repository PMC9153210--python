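import numpy as np
import pytest

from nuclei3d import IntensityVolume, SpecimenSpec, generate_specimen


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_volume(rng):
    """Small 12-bit random volume for oracle comparisons."""
    data = rng.integers(0, 4000, size=(12, 24, 24), dtype=np.uint16)
    return IntensityVolume(data=data, bit_depth=12)


@pytest.fixture(scope="session")
def default_specimen():
    """One default-condition specimen shared across tests (seed 1)."""
    return generate_specimen(SpecimenSpec(seed=1))
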