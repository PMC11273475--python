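import numpy as np
import pytest

from mihsim.phantom import TissueRegistry, VoxelPhantom, build_head_phantom
from mihsim.pipeline import RunConfig, run_pipeline


@pytest.fixture(scope="session")
def registry() -> TissueRegistry:
    return TissueRegistry.from_csv()


@pytest.fixture(scope="session")
def default_phantom() -> "VoxelPhantom":
    return build_head_phantom()


def make_block_phantom(
    shape=(8, 8, 8),
    tissue="mixed tissue",
    voxel_size=0.5e-3,
    air_margin=1,
) -> VoxelPhantom:
    """Homogeneous tissue block wrapped in an air margin, so that every
    tissue face sees the (default: insulated) surface condition rather than
    the fixed far-field boundary."""
    full = tuple(s + 2 * air_margin for s in shape)
    labels = np.zeros(full, dtype=np.uint8)
    core = tuple(slice(air_margin, air_margin + s) for s in shape)
    labels[core] = 1
    origin = -0.5 * voxel_size * (np.array(full) - 1)
    return VoxelPhantom(
        labels=labels,
        voxel_size=voxel_size,
        origin=origin,
        tissue_names=("air", tissue),
    )


@pytest.fixture
def block_phantom() -> VoxelPhantom:
    return make_block_phantom()


@pytest.fixture(scope="session")
def study_report():
    """The full default run (calibrated coil, 300 s exposure); shared by the
    pipeline and acceptance tests."""
    return run_pipeline(RunConfig(), write=False)
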