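import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_hr_grid():
    from locsrr.geometry import VoxelGrid

    return VoxelGrid.centered((8, 8, 8), 0.13)


@pytest.fixture
def small_geometry():
    from locsrr.geometry import AcquisitionGeometry

    return AcquisitionGeometry(
        angle_deg=0.0, in_plane_mm=0.1305, thickness_mm=0.52, shape=(8, 8, 2)
    )


def dense_matrix(op, hr_shape):
    """Explicit dense matrix of a forward operator, built column by column
    from unit impulses (independent oracle for linearity/adjoint tests)."""
    from locsrr.forward import HRImage

    n = int(np.prod(hr_shape))
    m = int(np.prod(op.geometry.shape))
    A = np.zeros((m, n))
    for j in range(n):
        e = np.zeros(n)
        e[j] = 1.0
        A[:, j] = op.apply(HRImage(op.hr_grid, e.reshape(hr_shape))).data.ravel()
    return A
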