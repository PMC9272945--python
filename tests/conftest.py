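import numpy as np
import pytest

from srrmri import AcquisitionGeometry, build_joint_system


@pytest.fixture(scope="session")
def geo_a3():
    """Aspect factor 3 on a 32^2 grid with the minimum 5 rotations."""
    return AcquisitionGeometry.protocol(3, 32)


@pytest.fixture(scope="session")
def joint_a3(geo_a3):
    return build_joint_system(geo_a3)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)


def centered_grid(n):
    idx = np.arange(n) - (n - 1) / 2
    return np.meshgrid(idx, idx)
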