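import numpy as np
import pytest

from brainmech import MegSpec, PhantomSpec, ProbeSpec

VOXEL = (2e-4, 2e-4, 3e-4)  # 0.2 x 0.2 mm in-plane, 0.3 mm slices


@pytest.fixture
def probe() -> ProbeSpec:
    return ProbeSpec()  # R = 6 um, k = 0.1 N/m, 33 nm/V, nu = 0.5


@pytest.fixture
def meg() -> MegSpec:
    return MegSpec()


def homogeneous_phantom(
    modulus: complex,
    shape=(32, 32, 8),
    voxel=VOXEL,
    polarization=(0.0, 2**-0.5, 2**-0.5),
    seed: int = 0,
    **kwargs,
) -> PhantomSpec:
    labels = np.ones(shape, dtype=np.int32)
    return PhantomSpec(
        grid_shape=shape,
        voxel_size=voxel,
        region_labels=labels,
        region_moduli={1: modulus},
        polarization=polarization,
        seed=seed,
        **kwargs,
    )


@pytest.fixture
def cortex_phantom() -> PhantomSpec:
    return homogeneous_phantom(8070 + 3200j)


def interior_roi(shape, margin=3, z_margin=2) -> np.ndarray:
    roi = np.zeros(shape, dtype=bool)
    roi[margin:-margin, margin:-margin, z_margin:-z_margin] = True
    return roi
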