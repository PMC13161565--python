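"""NIfTI input/output and canonical-orientation handling.

All images and masks are carried as :class:`ImageVolume` / :class:`BinaryMask`
in the RAS+ axis convention (indices increase toward the patient's Right,
Anterior, Superior).  Every downstream geometric operation — the rotation
sweep about the left/right, anterior/posterior and superior/inferior axes in
particular — assumes this convention, so volumes are reoriented on read.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np
from scipy import ndimage

from . import __version__


class VolumeError(ValueError):
    """Raised for structurally invalid image or mask inputs."""


@dataclass
class ImageVolume:
    """A 3D scalar image on a regular grid.

    Parameters
    ----------
    data
        3D array of intensities (arbitrary units).
    affine
        4x4 voxel-index -> world-mm map (RAS+ world frame).
    """

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise VolumeError(
                f"expected 3D volume, got {self.data.ndim}D payload"
            )
        if any(s < 1 for s in self.data.shape):
            raise VolumeError("every volume axis must have extent >= 1")
        if self.affine.shape != (4, 4):
            raise VolumeError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise VolumeError("affine is not invertible")
        if np.any(self.spacing <= 0):
            raise VolumeError("voxel spacing must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def spacing(self) -> np.ndarray:
        """Length of one grid step along each index axis, in mm."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    @property
    def axis_labels(self) -> tuple[str, str, str]:
        return nib.aff2axcodes(self.affine)

    @property
    def origin(self) -> np.ndarray:
        """World coordinates of the center of voxel (0, 0, 0)."""
        return self.affine[:3, 3].copy()

    def voxel_to_world(self, idx: np.ndarray) -> np.ndarray:
        """Map (N, 3) voxel indices to (N, 3) world mm coordinates."""
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        inv = np.linalg.inv(self.affine)
        return pts @ inv[:3, :3].T + inv[:3, 3]

    def is_axis_aligned(self, tol: float = 1e-6) -> bool:
        """True when the affine's linear part is diag(spacing) (RAS-aligned)."""
        return bool(
            np.allclose(self.affine[:3, :3], np.diag(self.spacing), atol=tol)
        )

    def same_grid(self, other: "ImageVolume", tol: float = 1e-4) -> bool:
        return self.shape == other.shape and bool(
            np.allclose(self.affine, other.affine, atol=tol)
        )

    def world_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Axis-aligned world box covered by the physical field of view.

        Voxels are treated as spacing-sized cells centered on the lattice, so
        the box extends half a voxel beyond the outermost voxel centers.
        """
        corners = np.array(
            [[i, j, k] for i in (0, self.shape[0] - 1)
             for j in (0, self.shape[1] - 1)
             for k in (0, self.shape[2] - 1)],
            dtype=float,
        )
        world = self.voxel_to_world(corners)
        half = 0.5 * self.spacing
        return world.min(axis=0) - half, world.max(axis=0) + half


@dataclass
class BinaryMask:
    """A {0,1} segmentation mask defined on a reference image grid."""

    data: np.ndarray
    grid: ImageVolume

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.shape != self.grid.shape:
            raise VolumeError(
                f"mask shape {self.data.shape} does not match its grid "
                f"{self.grid.shape}"
            )
        vals = np.unique(self.data)
        if not np.isin(vals, (0, 1)).all():
            raise VolumeError("mask values must be exactly {0, 1}")
        self.data = self.data.astype(np.uint8)
        self._coords_mm: Optional[np.ndarray] = None

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def volume_mm3(self) -> float:
        return self.n_voxels * float(np.prod(self.grid.spacing))

    @property
    def coords_mm(self) -> np.ndarray:
        """World coordinates (N, 3) of the nonzero voxel centers (cached)."""
        if self._coords_mm is None:
            idx = np.argwhere(self.data)
            self._coords_mm = np.ascontiguousarray(
                self.grid.voxel_to_world(idx)
                if idx.size
                else np.empty((0, 3), dtype=float)
            )
        return self._coords_mm


def read_volume(path: str | Path) -> ImageVolume:
    """Load a NIfTI volume and reorient it to the canonical RAS+ convention.

    4D payloads (e.g. time series) are rejected: a wrong-modality input should
    fail loudly rather than be silently squeezed.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(path)
    if img.ndim != 3:
        raise VolumeError(f"expected 3D volume, got {img.ndim}D payload: {path}")
    img = nib.as_closest_canonical(img)
    data = np.asanyarray(img.dataobj).astype(np.float64)
    return ImageVolume(data=data, affine=np.asarray(img.affine, dtype=float))


def read_mask(path: str | Path, reference: ImageVolume) -> BinaryMask:
    """Load a segmentation and put it on ``reference``'s grid.

    Values are binarized with a > 0.5 threshold.  A mask on a different grid
    is resampled onto the reference with nearest-neighbor interpolation only,
    so binarity and count-based volumes are preserved.
    """
    vol = read_volume(path)
    data = vol.data
    if np.isnan(data).all():
        raise VolumeError(f"mask payload is all-NaN: {path}")
    data = np.nan_to_num(data, nan=0.0)
    if vol.same_grid(reference):
        return BinaryMask(data=(data > 0.5).astype(np.uint8), grid=reference)
    # reference voxel index -> world -> source voxel index, nearest neighbor
    mapping = np.linalg.inv(vol.affine) @ reference.affine
    out = ndimage.affine_transform(
        (data > 0.5).astype(np.uint8),
        matrix=mapping[:3, :3],
        offset=mapping[:3, 3],
        output_shape=reference.shape,
        order=0,
        mode="constant",
        cval=0,
    )
    return BinaryMask(data=out.astype(np.uint8), grid=reference)


def write_volume(vol: ImageVolume, path: str | Path) -> Path:
    """Write an intensity volume as NIfTI (float32 payload)."""
    path = Path(path)
    img = nib.Nifti1Image(vol.data.astype(np.float32), vol.affine)
    nib.save(img, path)
    return path


def write_mask(mask: BinaryMask, path: str | Path) -> Path:
    """Write a binary mask as NIfTI with an unsigned 8-bit payload."""
    path = Path(path)
    img = nib.Nifti1Image(mask.data.astype(np.uint8), mask.grid.affine)
    nib.save(img, path)
    return path


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def write_report(report, path: str | Path) -> Path:
    """Serialize a :class:`~mrsplace.optimize.PlacementReport` to JSON.

    The file carries everything needed to reproduce and re-score the run:
    placement (world mm / degrees), enclosed-volume scores (mm^3), mode,
    fallback flag, the full search parameters and the software version.
    Output is byte-stable apart from the timestamp field.
    """
    path = Path(path)
    payload = {
        "software": {"name": "mrsplace", "version": __version__},
        "timestamp": _dt.datetime.now(_dt.timezone.utc).isoformat(),
        **report.to_dict(),
    }
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path


def parse_report(path: str | Path):
    """Inverse of :func:`write_report` (timestamp/software are metadata)."""
    from .optimize import PlacementReport

    payload = json.loads(Path(path).read_text())
    return PlacementReport.from_dict(payload)
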