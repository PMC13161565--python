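"""Synthetic ellipsoidal tumor phantoms.

The phantom stands in for clinical inputs: a post-contrast T1 volume with an
enhancing ellipsoidal core containing an interior necrotic ellipsoid, a FLAIR
volume with a surrounding hyperintense edema ellipsoid, plus the matching
ground-truth sub-compartment masks.  Ellipsoids (rather than realistic lesion
shapes) keep optimal placements geometrically interpretable, which is what
the test suite needs; they make no attempt at MR physics or texture realism.

Intensity levels are fixed (background 0, edema 60, core 100, necrosis 20,
arbitrary units) — the optimizer reads only masks; intensities exist so that
registration has something to align.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass


import numpy as np

from .geometry import rotation_matrix
from .io import BinaryMask, ImageVolume

INTENSITY = {"background": 0.0, "edema": 60.0, "core": 100.0, "necrosis": 20.0}

SUITE_NAMES = (
    "small_enhancing",
    "large_enhancing_with_necrosis",
    "non_enhancing",
    "core_larger_than_cube",
    "necrosis_everywhere",
)


@dataclass
class PhantomSpec:
    """Parameters of one synthetic tumor phantom.

    Radii are ellipsoid semi-axes in mm; a zero radius vector means the
    compartment is absent.  Nesting (necrosis <= core <= edema componentwise)
    is enforced so the generated masks satisfy the anatomical containment
    convention by construction.
    """

    shape: tuple[int, int, int] = (128, 128, 128)
    spacing_mm: float = 1.0
    core_center_mm: tuple[float, float, float] = (64.0, 64.0, 64.0)
    core_radii_mm: tuple[float, float, float] = (10.0, 10.0, 10.0)
    necrosis_radii_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    edema_radii_mm: tuple[float, float, float] = (15.0, 15.0, 15.0)
    core_rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    noise_sd: float = 0.0
    enhancing: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        core = np.asarray(self.core_radii_mm, dtype=float)
        nec = np.asarray(self.necrosis_radii_mm, dtype=float)
        edema = np.asarray(self.edema_radii_mm, dtype=float)
        if np.any(core < 0) or np.any(nec < 0) or np.any(edema < 0):
            raise ValueError("radii must be non-negative")
        if np.any(nec > core):
            raise ValueError("necrosis radii must not exceed core radii")
        if np.any(core > edema):
            raise ValueError("core radii must not exceed edema radii")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be non-negative")
        if self.spacing_mm <= 0:
            raise ValueError("spacing must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


def _ellipsoid_mask(
    coords_rel: np.ndarray, radii: np.ndarray, rot: np.ndarray
) -> np.ndarray:
    """Voxel-center membership of a rotated ellipsoid (||.|| <= 1)."""
    if np.any(radii <= 0):
        return np.zeros(coords_rel.shape[:-1], dtype=bool)
    body = coords_rel @ rot  # R^T (x - c), row form
    return ((body / radii) ** 2).sum(axis=-1) <= 1.0


def generate_phantom(spec: PhantomSpec):
    """Generate (t1c, flair, segmentation) for one phantom spec.

    The enhancing-core mask excludes the necrosis region (the two labels are
    mutually exclusive sub-compartments); the whole mask is the full edema
    ellipsoid.  For ``enhancing=False`` the core and necrosis masks are empty.
    Identical specs produce bit-identical outputs.
    """
    from .geometry import TumorSegmentation

    shape = tuple(int(s) for s in spec.shape)
    sp = float(spec.spacing_mm)
    affine = np.diag([sp, sp, sp, 1.0])
    ax = [np.arange(n) * sp for n in shape]
    gx, gy, gz = np.meshgrid(*ax, indexing="ij")
    coords = np.stack([gx, gy, gz], axis=-1) - np.asarray(spec.core_center_mm)
    rot = rotation_matrix(spec.core_rotation_deg)

    edema = _ellipsoid_mask(coords, np.asarray(spec.edema_radii_mm), rot)
    core_full = _ellipsoid_mask(coords, np.asarray(spec.core_radii_mm), rot)
    nec = _ellipsoid_mask(coords, np.asarray(spec.necrosis_radii_mm), rot)

    t1c_data = np.zeros(shape, dtype=np.float64)
    flair_data = np.zeros(shape, dtype=np.float64)
    flair_data[edema] = INTENSITY["edema"]
    t1c_data[core_full] = INTENSITY["core"]
    t1c_data[nec] = INTENSITY["necrosis"]

    if spec.enhancing:
        core_mask = core_full & ~nec
        nec_mask = nec
    else:
        core_mask = np.zeros(shape, dtype=bool)
        nec_mask = np.zeros(shape, dtype=bool)

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        t1c_data = t1c_data + rng.normal(0.0, spec.noise_sd, shape)
        flair_data = flair_data + rng.normal(0.0, spec.noise_sd, shape)

    t1c = ImageVolume(data=t1c_data, affine=affine.copy())
    flair = ImageVolume(data=flair_data, affine=affine.copy())
    seg = TumorSegmentation(
        core=BinaryMask(core_mask.astype(np.uint8), grid=t1c),
        necrosis=BinaryMask(nec_mask.astype(np.uint8), grid=t1c),
        whole=BinaryMask(edema.astype(np.uint8), grid=t1c),
    )
    return t1c, flair, seg


def phantom_suite(name: str) -> list[PhantomSpec]:
    """Fixed, seeded phantom families covering the optimizer's branches.

    - ``small_enhancing``: core fits inside the cube; many placements achieve
      full enclosure, so the edema tiebreaker decides.
    - ``large_enhancing_with_necrosis``: rotated anisotropic core with an
      interior necrotic region; the zero-necrosis constraint is active.
    - ``non_enhancing``: no contrast enhancement; FLAIR-only objective.
    - ``core_larger_than_cube``: every core diameter exceeds the 20 mm cube,
      so only partial enclosure is attainable.
    - ``necrosis_everywhere``: necrosis covers every admissible cube position
      (48^3 grid so the search space is small enough for exhaustive
      verification), forcing the flagged fallback objective.
    """
    if name == "small_enhancing":
        return [
            PhantomSpec(
                core_center_mm=(64.0, 64.0, 64.0),
                core_radii_mm=(8.0, 8.0, 8.0),
                necrosis_radii_mm=(0.0, 0.0, 0.0),
                edema_radii_mm=(14.0, 14.0, 14.0),
                noise_sd=2.0,
                seed=101,
            )
        ]
    if name == "large_enhancing_with_necrosis":
        return [
            PhantomSpec(
                core_center_mm=(60.0, 66.0, 62.0),
                core_radii_mm=(15.0, 12.0, 14.0),
                necrosis_radii_mm=(6.0, 5.0, 6.0),
                edema_radii_mm=(17.0, 15.0, 16.0),
                core_rotation_deg=(20.0, 10.0, 30.0),
                noise_sd=2.0,
                seed=202,
            )
        ]
    if name == "non_enhancing":
        return [
            PhantomSpec(
                enhancing=False,
                core_center_mm=(66.0, 60.0, 64.0),
                core_radii_mm=(0.0, 0.0, 0.0),
                necrosis_radii_mm=(0.0, 0.0, 0.0),
                edema_radii_mm=(15.0, 12.0, 10.0),
                core_rotation_deg=(0.0, 15.0, 0.0),
                noise_sd=2.0,
                seed=303,
            )
        ]
    if name == "core_larger_than_cube":
        return [
            PhantomSpec(
                core_center_mm=(64.0, 62.0, 66.0),
                core_radii_mm=(16.0, 13.0, 12.0),
                necrosis_radii_mm=(4.0, 3.0, 3.0),
                edema_radii_mm=(19.0, 16.0, 15.0),
                core_rotation_deg=(10.0, 25.0, 5.0),
                noise_sd=2.0,
                seed=404,
            )
        ]
    if name == "necrosis_everywhere":
        return [
            PhantomSpec(
                shape=(48, 48, 48),
                core_center_mm=(23.5, 23.5, 23.5),
                core_radii_mm=(30.0, 30.0, 30.0),
                necrosis_radii_mm=(28.0, 28.0, 28.0),
                edema_radii_mm=(32.0, 32.0, 32.0),
                noise_sd=1.0,
                seed=505,
            )
        ]
    raise ValueError(
        f"unknown phantom suite {name!r}; known: {', '.join(SUITE_NAMES)}"
    )
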