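"""Cube geometry, search-space construction and exact enclosed-volume scoring.

The MRS acquisition volume is a cube of fixed side (default 20 mm, i.e. the
clinical 2 x 2 x 2 cm^3 voxel) placed at a world-space center and rotated
about the canonical left/right (x), anterior/posterior (y) and
superior/inferior (z) axes by angles in [0, 90] degrees.

Scoring is defined combinatorially on the common 1 mm isotropic grid: a grid
voxel is enclosed iff its *center* lies inside the cube, and enclosed volume
is the count of such voxels times 1 mm^3.  Cube membership is half-open
([-s/2, s/2) per axis in the cube frame) so an axis-aligned cube at an
integer center encloses exactly side^3 voxels and opposite faces never
double-count a boundary voxel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .io import BinaryMask, ImageVolume

#: Search-space pad around the target bounding box: 2*sqrt(3) cm, kept at
#: full floating precision.
PAD_DEFAULT_MM: float = 2.0 * np.sqrt(3.0) * 10.0

#: Clinical single-voxel MRS cube side (2 cm).
SIDE_DEFAULT_MM: float = 20.0

# Both half-open bounds are shifted inward by this amount so that exact
# boundary ties (which occur on rational-center lattices) are decided
# identically by every counting path.  True voxel-center distances to a cube
# face are never below ~0.25 mm on such lattices, so no non-tie voxel can be
# reclassified.
MEMBERSHIP_EPS_MM: float = 1e-6

SCORING_SPACING_MM: float = 1.0


class EmptyMaskError(ValueError):
    """Raised when an operation requires a nonempty mask."""


class GridError(ValueError):
    """Raised when masks are not on the common isotropic scoring grid."""


@dataclass
class CubePlacement:
    """Pose of the MRS acquisition cube.

    ``center_mm`` is in world (RAS+) coordinates; ``angles_deg`` are extrinsic
    rotations about the fixed x (L/R), y (A/P), z (S/I) axes, composed in that
    order; rotation is about the cube center.
    """

    center_mm: np.ndarray
    angles_deg: np.ndarray
    side_mm: float = SIDE_DEFAULT_MM

    def __post_init__(self) -> None:
        self.center_mm = np.asarray(self.center_mm, dtype=float).reshape(3)
        self.angles_deg = np.asarray(self.angles_deg, dtype=float).reshape(3)
        if self.side_mm <= 0:
            raise ValueError("cube side must be positive")
        if np.any(self.angles_deg < 0) or np.any(self.angles_deg > 90):
            raise ValueError("rotation angles must lie in [0, 90] degrees")

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, CubePlacement)
            and np.array_equal(self.center_mm, other.center_mm)
            and np.array_equal(self.angles_deg, other.angles_deg)
            and self.side_mm == other.side_mm
        )


@dataclass
class TumorSegmentation:
    """Tumor sub-compartment masks on one shared grid.

    ``core`` is the contrast-enhancing compartment, ``necrosis`` the central
    non-viable compartment (disjoint from core by convention), ``whole`` the
    full FLAIR-hyperintense extent.  At least one of core/whole must be
    present.
    """

    core: Optional[BinaryMask] = None
    necrosis: Optional[BinaryMask] = None
    whole: Optional[BinaryMask] = None

    def __post_init__(self) -> None:
        if self.core is None and self.whole is None:
            raise ValueError("at least one of core/whole must be present")
        grids = [m.grid for m in self.masks().values()]
        for g in grids[1:]:
            if not grids[0].same_grid(g):
                raise GridError("all segmentation masks must share one grid")
        self._stacked: Optional[tuple[np.ndarray, dict[str, slice]]] = None

    def masks(self) -> dict[str, BinaryMask]:
        out = {}
        for name in ("core", "necrosis", "whole"):
            m = getattr(self, name)
            if m is not None:
                out[name] = m
        return out

    @property
    def grid(self) -> ImageVolume:
        return next(iter(self.masks().values())).grid

    def _stacked_coords(self) -> tuple[np.ndarray, dict[str, slice]]:
        """All mask voxel-center coordinates stacked, with per-mask slices."""
        if self._stacked is None:
            parts, slices, start = [], {}, 0
            for name, m in self.masks().items():
                c = m.coords_mm
                parts.append(c)
                slices[name] = slice(start, start + len(c))
                start += len(c)
            coords = (
                np.concatenate(parts, axis=0)
                if parts
                else np.empty((0, 3), dtype=float)
            )
            self._stacked = (np.ascontiguousarray(coords), slices)
        return self._stacked


@dataclass
class PlacementScore:
    """Enclosed sub-compartment volumes (mm^3) for one placement."""

    core_mm3: int = 0
    necrosis_mm3: int = 0
    whole_mm3: int = 0

    @property
    def feasible(self) -> bool:
        """A placement is feasible iff it encloses zero necrosis."""
        return self.necrosis_mm3 == 0

    def to_dict(self) -> dict:
        return {
            "core_mm3": int(self.core_mm3),
            "necrosis_mm3": int(self.necrosis_mm3),
            "whole_mm3": int(self.whole_mm3),
            "feasible": self.feasible,
        }


@dataclass
class SearchSpace:
    """Admissible cube centers and rotations around a target segmentation.

    Candidate centers form a regular lattice with spacing ``center_stride_mm``
    inside the target bounding box padded by ``pad_mm`` on every side,
    restricted to positions where the rotated cube's circumscribing sphere
    (radius side*sqrt(3)/2) stays inside the image field of view.  The lattice
    is centered on the box midpoint, so it is symmetric under the grid's
    lattice symmetries.  Candidate angles per axis are {0, step, 2*step, ...}
    with 90 always included.

    Iteration order over candidates is centers ascending by (x, y, z), then
    angle triples ascending by (ax, ay, az).
    """

    target_bbox_mm: tuple[np.ndarray, np.ndarray]
    pad_mm: float
    center_stride_mm: float
    angle_step_deg: float
    side_mm: float
    image_domain: tuple[np.ndarray, np.ndarray]
    center_axes: tuple[np.ndarray, np.ndarray, np.ndarray]
    angle_axis: np.ndarray

    @property
    def center_box_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """Center-limit box: target bbox padded by ``pad_mm`` per side."""
        lo, hi = self.target_bbox_mm
        return lo - self.pad_mm, hi + self.pad_mm

    @property
    def n_centers(self) -> int:
        return int(np.prod([len(a) for a in self.center_axes]))

    @property
    def n_angles(self) -> int:
        return len(self.angle_axis) ** 3

    @property
    def n_candidates(self) -> int:
        return self.n_centers * self.n_angles

    def centers(self) -> np.ndarray:
        """All candidate centers, (M, 3), ascending by (x, y, z)."""
        gx, gy, gz = np.meshgrid(*self.center_axes, indexing="ij")
        return np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

    def angles(self) -> np.ndarray:
        """All candidate angle triples, (K, 3), ascending by (ax, ay, az)."""
        a = self.angle_axis
        gx, gy, gz = np.meshgrid(a, a, a, indexing="ij")
        return np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

    def to_dict(self) -> dict:
        lo, hi = self.target_bbox_mm
        dlo, dhi = self.image_domain
        return {
            "target_bbox_mm": {"lo": lo.tolist(), "hi": hi.tolist()},
            "pad_mm": float(self.pad_mm),
            "center_stride_mm": float(self.center_stride_mm),
            "angle_step_deg": float(self.angle_step_deg),
            "side_mm": float(self.side_mm),
            "image_domain": {"lo": dlo.tolist(), "hi": dhi.tolist()},
            "n_centers": self.n_centers,
            "n_angles": self.n_angles,
        }


def rotation_matrix(angles_deg) -> np.ndarray:
    """Rotation for extrinsic X (L/R), then Y (A/P), then Z (S/I) rotations.

    Returns R = Rz @ Ry @ Rx; columns are the cube's body axes in world
    coordinates.  Cube-frame coordinates of a world point p are
    ``R.T @ (p - center)``.
    """
    a = np.asarray(angles_deg, dtype=float).reshape(3)
    ax, ay, az = np.deg2rad(a)
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    # closed form of Rz @ Ry @ Rx
    return np.array(
        [
            [cz * cy, cz * sy * sx - sz * cx, cz * sy * cx + sz * sx],
            [sz * cy, sz * sy * sx + cz * cx, sz * sy * cx - cz * sx],
            [-sy, cy * sx, cy * cx],
        ]
    )


def compute_bbox(mask: BinaryMask) -> tuple[np.ndarray, np.ndarray]:
    """Tightest axis-aligned world box containing all nonzero voxel centers."""
    if mask.n_voxels == 0:
        raise EmptyMaskError("cannot compute bounding box of an empty mask")
    coords = mask.coords_mm
    return coords.min(axis=0), coords.max(axis=0)


def cube_membership(points_mm: np.ndarray, placement: CubePlacement) -> np.ndarray:
    """Boolean half-open cube membership for (N, 3) world points.

    A point x is inside iff every component of q = R^T (x - c) satisfies
    -side/2 <= q < side/2 (with the tie-stabilizing inward epsilon shift).
    """
    r = rotation_matrix(placement.angles_deg)
    # row-vector form of R^T (x - c); per-axis matvecs keep outputs contiguous
    o = np.asarray(points_mm, dtype=float) - placement.center_mm
    half = placement.side_mm / 2.0
    lo = -half - MEMBERSHIP_EPS_MM
    hi = half - MEMBERSHIP_EPS_MM
    q = o @ r[:, 0]
    inside = (q >= lo) & (q < hi)
    q = o @ r[:, 1]
    inside &= (q >= lo) & (q < hi)
    q = o @ r[:, 2]
    inside &= (q >= lo) & (q < hi)
    return inside


try:  # jitted hot path for per-placement scoring; numpy fallback otherwise
    import numba

    @numba.njit(cache=True, fastmath=True)
    def _count_in_cube_jit(coords, r, center, lo, hi, bounds):  # pragma: no cover
        # branchless inner loop so the compiler can vectorize; fastmath
        # reassociation cannot flip the predicate because boundary ties only
        # occur where every product is exactly representable
        counts = np.zeros(len(bounds) - 1, dtype=np.int64)
        r00, r10, r20 = r[0, 0], r[1, 0], r[2, 0]
        r01, r11, r21 = r[0, 1], r[1, 1], r[2, 1]
        r02, r12, r22 = r[0, 2], r[1, 2], r[2, 2]
        for b in range(len(bounds) - 1):
            n = 0
            for i in range(bounds[b], bounds[b + 1]):
                ox = coords[i, 0] - center[0]
                oy = coords[i, 1] - center[1]
                oz = coords[i, 2] - center[2]
                q0 = ox * r00 + oy * r10 + oz * r20
                q1 = ox * r01 + oy * r11 + oz * r21
                q2 = ox * r02 + oy * r12 + oz * r22
                inside = (
                    (q0 >= lo)
                    and (q0 < hi)
                    and (q1 >= lo)
                    and (q1 < hi)
                    and (q2 >= lo)
                    and (q2 < hi)
                )
                n += 1 if inside else 0
            counts[b] = n
        return counts

except Exception:  # pragma: no cover
    _count_in_cube_jit = None


def _require_scoring_grid(seg: TumorSegmentation) -> None:
    if getattr(seg, "_scoring_grid_ok", False):
        return
    grid = seg.grid
    if not np.allclose(grid.spacing, SCORING_SPACING_MM, atol=1e-6):
        raise GridError(
            "scoring is defined on the resampled 1 mm isotropic grid; "
            f"got spacing {grid.spacing}"
        )
    if not grid.is_axis_aligned():
        raise GridError("scoring grid must be RAS axis-aligned")
    seg._scoring_grid_ok = True


def score_placement(placement: CubePlacement, seg: TumorSegmentation) -> PlacementScore:
    """Exact enclosed volume of each sub-compartment for one placement.

    Counts nonzero grid-voxel centers inside the cube; on the 1 mm grid one
    count equals 1 mm^3.  Absent masks score 0.
    """
    _require_scoring_grid(seg)
    coords, slices = seg._stacked_coords()
    counts = {"core": 0, "necrosis": 0, "whole": 0}
    if len(coords):
        half = placement.side_mm / 2.0
        if _count_in_cube_jit is not None:
            bounds = np.array(
                [sl.start for sl in slices.values()] + [len(coords)],
                dtype=np.int64,
            )
            per_mask = _count_in_cube_jit(
                coords,
                rotation_matrix(placement.angles_deg),
                placement.center_mm,
                -half - MEMBERSHIP_EPS_MM,
                half - MEMBERSHIP_EPS_MM,
                bounds,
            )
            for name, c in zip(slices.keys(), per_mask):
                counts[name] = int(c)
        else:
            inside = cube_membership(coords, placement)
            for name, sl in slices.items():
                counts[name] = int(np.count_nonzero(inside[sl]))
    return PlacementScore(
        core_mm3=counts["core"],
        necrosis_mm3=counts["necrosis"],
        whole_mm3=counts["whole"],
    )


def rasterize_cube(placement: CubePlacement, grid: ImageVolume) -> BinaryMask:
    """Rasterize the cube onto an image grid as a binary mask.

    Uses the same half-open voxel-center membership as
    :func:`score_placement`, so for any mask m on the same grid,
    ``count(rasterize & m) == score``.
    """
    reach = placement.side_mm * np.sqrt(3.0) / 2.0 + np.max(grid.spacing)
    lo_idx = np.floor(
        grid.world_to_voxel(placement.center_mm - reach)
    ).astype(int).reshape(3)
    hi_idx = np.ceil(
        grid.world_to_voxel(placement.center_mm + reach)
    ).astype(int).reshape(3)
    lo_idx = np.maximum(lo_idx, 0)
    hi_idx = np.minimum(hi_idx, np.array(grid.shape) - 1)
    data = np.zeros(grid.shape, dtype=np.uint8)
    if np.any(lo_idx > hi_idx):
        warnings.warn("cube lies entirely outside the image grid")
        return BinaryMask(data=data, grid=grid)
    axes = [np.arange(lo_idx[d], hi_idx[d] + 1) for d in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    idx = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    inside = cube_membership(grid.voxel_to_world(idx), placement)
    if not inside.any():
        warnings.warn("cube lies entirely outside the image grid")
        return BinaryMask(data=data, grid=grid)
    sel = idx[inside]
    data[sel[:, 0], sel[:, 1], sel[:, 2]] = 1
    return BinaryMask(data=data, grid=grid)


def _angle_axis(step_deg: float) -> np.ndarray:
    if not (0 < step_deg <= 90):
        raise ValueError("angle step must be in (0, 90] degrees")
    vals = list(np.arange(0.0, 90.0, step_deg))
    if not np.isclose(vals[-1], 90.0):
        vals.append(90.0)
    else:  # pragma: no cover - arange never includes the endpoint
        vals[-1] = 90.0
    return np.asarray(vals)


def build_search_space(
    target: BinaryMask,
    *,
    pad_mm: float = PAD_DEFAULT_MM,
    center_stride_mm: float = 2.0,
    angle_step_deg: float = 15.0,
    side_mm: float = SIDE_DEFAULT_MM,
) -> SearchSpace:
    """Construct the candidate center lattice and angle grid for a target.

    The center-limit box is the target's bounding box padded by ``pad_mm``
    per side.  The lattice with the requested stride is centered on the box
    midpoint and clipped to centers where the cube's circumscribing sphere
    fits inside the image field of view.
    """
    if pad_mm < 0:
        raise ValueError("pad must be non-negative")
    if center_stride_mm <= 0:
        raise ValueError("center stride must be positive")
    lo, hi = compute_bbox(target)
    angle_axis = _angle_axis(angle_step_deg)
    dom_lo, dom_hi = target.grid.world_bounds()
    r_circ = side_mm * np.sqrt(3.0) / 2.0
    axes = []
    for d in range(3):
        extent = hi[d] - lo[d]
        # symmetric lattice mid + k*stride, k in [-m, m]: maps onto itself
        # under the grid's lattice symmetries and is nested under stride
        # halving; all candidates stay inside the padded box
        m = int(np.floor((extent / 2.0 + pad_mm) / center_stride_mm))
        mid = 0.5 * (lo[d] + hi[d])
        vals = mid + np.arange(-m, m + 1) * center_stride_mm
        vals = vals[(vals - r_circ >= dom_lo[d]) & (vals + r_circ <= dom_hi[d])]
        if len(vals) == 0:
            raise ValueError(
                "empty candidate set: the rotated cube cannot fit inside the "
                f"image domain along axis {d}"
            )
        axes.append(vals)
    return SearchSpace(
        target_bbox_mm=(lo, hi),
        pad_mm=float(pad_mm),
        center_stride_mm=float(center_stride_mm),
        angle_step_deg=float(angle_step_deg),
        side_mm=float(side_mm),
        image_domain=(dom_lo, dom_hi),
        center_axes=tuple(axes),
        angle_axis=angle_axis,
    )
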