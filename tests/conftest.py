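import numpy as np
import pytest

from mrsplace.io import BinaryMask, ImageVolume
from mrsplace.geometry import TumorSegmentation
from mrsplace.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """Compact rotated enhancing phantom with necrosis on a 64^3 grid."""
    spec = PhantomSpec(
        shape=(64, 64, 64),
        core_center_mm=(32.0, 30.0, 33.0),
        core_radii_mm=(9.0, 8.0, 7.0),
        necrosis_radii_mm=(4.0, 3.0, 3.0),
        edema_radii_mm=(12.0, 11.0, 10.0),
        core_rotation_deg=(15.0, 25.0, 40.0),
        noise_sd=1.0,
        seed=7,
    )
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def small_seg(small_phantom):
    return small_phantom[2]


def make_mask(data, spacing=1.0, origin=(0.0, 0.0, 0.0)):
    """Binary mask on an axis-aligned grid with the given spacing/origin."""
    data = np.asarray(data, dtype=np.uint8)
    affine = np.diag([spacing, spacing, spacing, 1.0])
    affine[:3, 3] = origin
    grid = ImageVolume(data=np.zeros(data.shape), affine=affine)
    return BinaryMask(data=data, grid=grid)


def seg_from_arrays(core=None, necrosis=None, whole=None, spacing=1.0):
    kw = {}
    for name, arr in (("core", core), ("necrosis", necrosis), ("whole", whole)):
        if arr is not None:
            kw[name] = make_mask(arr, spacing=spacing)
    # share one grid object
    grids = [m.grid for m in kw.values()]
    for m in kw.values():
        m.grid = grids[0]
    return TumorSegmentation(**kw)
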