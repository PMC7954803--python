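import numpy as np
import pytest

from histoconcord import ImageGeometry, VoxelMask
from histoconcord.synthetic_phantom import generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Four default-profile phantom patients with ground truth."""
    return generate_cohort(n_patients=4, master_seed=11)


def random_gland(seed: int, shape=(32, 32, 16), spacing=(1.5, 1.5, 2.5)) -> VoxelMask:
    """Seeded random gland: an ellipsoid with boundary voxel noise."""
    rng = np.random.default_rng(seed)
    geom = ImageGeometry(shape=shape, spacing=spacing)
    center = np.array(
        [(shape[i] - 1) / 2 * spacing[i] for i in range(3)]
    ) + rng.uniform(-2, 2, 3)
    semis = np.array(
        [
            rng.uniform(0.25, 0.42) * shape[i] * spacing[i]
            for i in range(3)
        ]
    )
    x = geom.axis_coords(0)[:, None, None]
    y = geom.axis_coords(1)[None, :, None]
    z = geom.axis_coords(2)[None, None, :]
    q = (
        ((x - center[0]) / semis[0]) ** 2
        + ((y - center[1]) / semis[1]) ** 2
        + ((z - center[2]) / semis[2]) ** 2
    )
    occ = q <= 1.0
    # roughen the surface so glands are not perfectly symmetric
    shell = (q > 0.8) & (q <= 1.0)
    occ &= ~(shell & (rng.random(shape) < 0.3))
    return VoxelMask(geometry=geom, occupancy=occ, label="gland")


@pytest.fixture
def gland_factory():
    return random_gland
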