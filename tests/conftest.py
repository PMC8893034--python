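import numpy as np
import pytest

from lesionload import (
    LesionMask,
    SyntheticConfig,
    Tract,
    TractAtlas,
    VolumeGrid,
    make_atlas,
    make_cohort,
)


@pytest.fixture(scope="session")
def small_atlas() -> TractAtlas:
    """Two-region toy atlas on a 6x6x6 grid: M1 (20 voxels) and PMv (10)
    per hemisphere, hand-placed so brute-force voxel loops are feasible."""
    shape = (6, 6, 6)
    m1_l = np.zeros(shape, dtype=bool)
    m1_l[0:2, 0:2, 0:5] = True  # 20 voxels
    pmv_l = np.zeros(shape, dtype=bool)
    pmv_l[0:2, 4:5, 0:5] = True  # 10 voxels
    tracts = [
        Tract("M1", "L", m1_l),
        Tract("M1", "R", m1_l[::-1]),
        Tract("PMv", "L", pmv_l),
        Tract("PMv", "R", pmv_l[::-1]),
    ]
    grid = VolumeGrid(np.zeros(shape, dtype=np.int64), (2.0, 2.0, 2.0), "toy")
    return TractAtlas(tracts, grid)


def mask_from_voxels(shape, voxels, hemisphere="L", patient_id="p", voxel_size=(2.0, 2.0, 2.0)):
    vals = np.zeros(shape, dtype=np.int64)
    for v in voxels:
        vals[v] = 1
    return LesionMask(VolumeGrid(vals, voxel_size, "toy"), hemisphere, patient_id)


@pytest.fixture(scope="session")
def default_atlas():
    return make_atlas()


@pytest.fixture(scope="session")
def default_cohort():
    """One 34-patient synthetic cohort with masks, shared across tests."""
    return make_cohort(SyntheticConfig(master_seed=7))
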