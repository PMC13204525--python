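import numpy as np
import pytest

from dpetfusion.io import RoiMask, Volume
from dpetfusion.synthetic import GeneratorConfig, generate_case


@pytest.fixture(scope="session")
def default_config() -> GeneratorConfig:
    return GeneratorConfig()


@pytest.fixture(scope="session")
def synthetic_case(default_config):
    """One deterministic PET-like case shared across tests."""
    return generate_case(default_config, label=1, seed=7)


@pytest.fixture
def ellipsoid_pair():
    """A small analytic volume/mask pair with a graded ellipsoid."""
    shape = (20, 22, 24)
    zz, yy, xx = np.indices(shape, dtype=float)
    d = np.sqrt(((zz - 10) / 6) ** 2 + ((yy - 11) / 7) ** 2 + ((xx - 12) / 8) ** 2)
    vol = Volume(np.exp(-d) * 10 + 1.0)
    mask = RoiMask(d <= 1.0)
    return vol, mask


@pytest.fixture
def rng():
    return np.random.default_rng(123)
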