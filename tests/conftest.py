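import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hippoasym.io import BinaryMask
from hippoasym.synthetic import CohortConfig, generate_measurement_cohort

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_ball_mask(radius: int, spacing=(1.0, 1.0, 1.0)) -> BinaryMask:
    """Voxelized ball: voxel centers within `radius` of the origin."""
    g = np.arange(-radius - 2, radius + 3)
    x, y, z = np.meshgrid(g * spacing[0], g * spacing[1], g * spacing[2],
                          indexing="ij")
    return BinaryMask(x**2 + y**2 + z**2 <= radius**2, spacing)


@pytest.fixture(scope="session")
def ball15() -> BinaryMask:
    return make_ball_mask(15)


@pytest.fixture(scope="session")
def default_cohort():
    """One default-size synthetic cohort (406 HC + 126 patient scans)."""
    return generate_measurement_cohort(CohortConfig(seed=1234))
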