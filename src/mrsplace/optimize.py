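"""Exhaustive placement search, brute-force reference oracle and heatmaps.

Objective (enhancing mode): over all candidate placements restricted to
feasible ones (zero enclosed necrosis), maximize the lexicographic key
(enclosed core volume, enclosed whole-tumor volume).  Remaining ties are
broken by the earliest candidate in the deterministic iteration order
(centers ascending by (x, y, z), then angle triples ascending).  If no
feasible candidate exists, a flagged fallback maximizes
(-necrosis, core, whole) instead — a clinical user still needs a proposal.
FLAIR-only mode simply maximizes enclosed whole-tumor volume.

The production search counts enclosed voxels per rotation with an exact
FFT cross-correlation of the mask against a rasterized cube kernel; the
brute-force oracle is a literal per-candidate loop over
:func:`~mrsplace.geometry.score_placement`.  Both use the same half-open
voxel-center membership, so they agree integer-exactly — the test suite
enforces this equivalence.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Optional

import numpy as np
from scipy.signal import fftconvolve

from .geometry import (
    MEMBERSHIP_EPS_MM,
    PAD_DEFAULT_MM,
    SIDE_DEFAULT_MM,
    CubePlacement,
    PlacementScore,
    SearchSpace,
    TumorSegmentation,
    _require_scoring_grid,
    build_search_space,
    rotation_matrix,
    score_placement,
)
from .io import BinaryMask, ImageVolume

ORACLE_GUARD = 1_000_000


class ModeError(ValueError):
    """Raised when the masks required by the selected mode are missing."""


class InfeasibleError(RuntimeError):
    """No necrosis-free placement exists and the fallback is forbidden."""


@dataclass
class PlacementConfig:
    """Tunable search parameters.

    Defaults: 2 mm center stride and 15 degree angle step (7 angles per axis,
    343 rotations) give desk-scale runtimes while neighboring candidates
    change the enclosed volume by well under one cube face;
    ``min_core_mm3=100`` makes mode selection robust to speckle in the
    segmentation inputs.
    """

    center_stride_mm: float = 2.0
    angle_step_deg: float = 15.0
    pad_mm: float = PAD_DEFAULT_MM
    side_mm: float = SIDE_DEFAULT_MM
    min_core_mm3: float = 100.0
    heatmap: str = "identity"  # off | identity | optimal
    fallback: str = "allow"  # allow | forbid

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PlacementReport:
    """Result of one placement search."""

    placement: CubePlacement
    score: PlacementScore
    mode: str
    fallback_used: bool
    search: dict
    n_candidates_evaluated: int

    def to_dict(self) -> dict:
        return {
            "placement": {
                "center_mm": self.placement.center_mm.tolist(),
                "angles_deg": self.placement.angles_deg.tolist(),
                "side_mm": float(self.placement.side_mm),
            },
            "score": self.score.to_dict(),
            "mode": self.mode,
            "fallback_used": bool(self.fallback_used),
            "search": self.search,
            "n_candidates_evaluated": int(self.n_candidates_evaluated),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PlacementReport":
        p = d["placement"]
        s = d["score"]
        return cls(
            placement=CubePlacement(
                center_mm=np.asarray(p["center_mm"], dtype=float),
                angles_deg=np.asarray(p["angles_deg"], dtype=float),
                side_mm=float(p["side_mm"]),
            ),
            score=PlacementScore(
                core_mm3=int(s["core_mm3"]),
                necrosis_mm3=int(s["necrosis_mm3"]),
                whole_mm3=int(s["whole_mm3"]),
            ),
            mode=d["mode"],
            fallback_used=bool(d["fallback_used"]),
            search=d["search"],
            n_candidates_evaluated=int(d["n_candidates_evaluated"]),
        )


@dataclass
class Heatmap:
    """Enclosed target volume over the candidate-center lattice.

    ``values[i, j, k]`` is the enclosed core (enhancing) or whole-tumor
    (FLAIR-only) volume in mm^3 for a cube centered at
    ``(center_axes[0][i], center_axes[1][j], center_axes[2][k])`` at the
    fixed ``rotation_deg``; ``valid`` is False where the placement encloses
    necrosis (infeasible positions stay uncolored).
    """

    values: np.ndarray
    valid: np.ndarray
    rotation_deg: np.ndarray
    target: str
    center_axes: tuple[np.ndarray, np.ndarray, np.ndarray]
    side_mm: float


def select_mode(seg: TumorSegmentation, min_core_mm3: float = 100.0) -> str:
    """Choose the optimization mode from the available masks.

    Enhancing mode needs a core mask with at least ``min_core_mm3`` of
    enhancing volume; everything else falls through to FLAIR-only mode,
    which requires the whole-tumor mask.
    """
    core_vol = seg.core.volume_mm3 if seg.core is not None else 0.0
    if seg.core is not None and core_vol >= min_core_mm3:
        return "enhancing"
    if seg.whole is None:
        raise ModeError(
            "FLAIR-only mode selected (core absent or below threshold) but "
            "no whole-tumor mask is present"
        )
    return "flair_only"


# ---------------------------------------------------------------------------
# per-rotation enclosed-voxel counting


def _lattice_is_integer(space: SearchSpace) -> bool:
    s = space.center_stride_mm
    return abs(s - round(s)) < 1e-9 and round(s) >= 1


def _fft_counts(
    mask: BinaryMask, angles_deg, space: SearchSpace
) -> np.ndarray:
    """Exact enclosed-voxel counts for every lattice center at one rotation.

    Counting a rotated cube's enclosed voxels at every center of an
    integer-stride lattice is a cross-correlation of the mask with a cube
    membership kernel rasterized on the offset lattice.  FFT round-off is
    orders of magnitude below 0.5, so rounding recovers the exact integers.
    """
    shape = tuple(len(a) for a in space.center_axes)
    if mask.n_voxels == 0:
        return np.zeros(shape, dtype=np.int64)
    stride = int(round(space.center_stride_mm))
    nz = np.argwhere(mask.data)
    i_lo = nz.min(axis=0)
    i_hi = nz.max(axis=0)
    sub = mask.data[
        i_lo[0] : i_hi[0] + 1, i_lo[1] : i_hi[1] + 1, i_lo[2] : i_hi[2] + 1
    ].astype(np.float64)

    c0 = np.array([a[0] for a in space.center_axes])
    base = mask.grid.origin + i_lo.astype(float) - c0
    reach = space.side_mm * np.sqrt(3.0) / 2.0 + 1.0
    u_lo = np.ceil(-reach - base).astype(int)
    u_hi = np.floor(reach - base).astype(int)
    uax = [np.arange(u_lo[d], u_hi[d] + 1) for d in range(3)]
    ux, uy, uz = np.meshgrid(*uax, indexing="ij")
    offsets = np.stack([ux, uy, uz], axis=-1).astype(float) + base
    r = rotation_matrix(angles_deg)
    q = offsets.reshape(-1, 3) @ r
    half = space.side_mm / 2.0
    inside = (
        (q >= -half - MEMBERSHIP_EPS_MM) & (q < half - MEMBERSHIP_EPS_MM)
    ).all(axis=1)
    kernel = inside.reshape(ux.shape).astype(np.float64)

    corr = fftconvolve(sub, kernel[::-1, ::-1, ::-1], mode="full")
    # corr[p] = sum_i sub[i] * kernel[i - p + (nk - 1)]; the count for lattice
    # index k lives at p = k*stride + u_lo + nk - 1 along each axis.
    nk = np.array(kernel.shape)
    counts = np.zeros(shape, dtype=np.int64)
    pax, valid = [], []
    for d in range(3):
        p = np.arange(shape[d]) * stride + u_lo[d] + nk[d] - 1
        ok = (p >= 0) & (p < corr.shape[d])
        pax.append(p[ok])
        valid.append(np.flatnonzero(ok))
    if all(len(p) for p in pax):
        block = corr[np.ix_(*pax)]
        counts[np.ix_(*valid)] = np.maximum(
            np.rint(block), 0.0
        ).astype(np.int64)
    return counts


def _direct_counts(
    mask: BinaryMask, angles_deg, space: SearchSpace
) -> np.ndarray:
    """Per-candidate counting fallback for non-integer strides."""
    shape = tuple(len(a) for a in space.center_axes)
    counts = np.zeros(shape, dtype=np.int64)
    if mask.n_voxels == 0:
        return counts
    coords = mask.coords_mm
    order = np.argsort(coords[:, 0], kind="stable")
    xs = coords[order, 0]
    r = rotation_matrix(angles_deg)
    half = space.side_mm / 2.0
    qlo, qhi = -half - MEMBERSHIP_EPS_MM, half - MEMBERSHIP_EPS_MM
    reach = space.side_mm * np.sqrt(3.0) / 2.0 + 1e-9
    flat = counts.reshape(-1)
    for i, c in enumerate(space.centers()):
        a = np.searchsorted(xs, c[0] - reach)
        b = np.searchsorted(xs, c[0] + reach)
        if a == b:
            continue
        q = (coords[order[a:b]] - c) @ r
        flat[i] = int(((q >= qlo) & (q < qhi)).all(axis=1).sum())
    return counts


def _rotation_counts(mask, angles_deg, space) -> np.ndarray:
    if _lattice_is_integer(space):
        return _fft_counts(mask, angles_deg, space)
    return _direct_counts(mask, angles_deg, space)


# ---------------------------------------------------------------------------
# search


def _space_for_mode(
    seg: TumorSegmentation, mode: str, cfg: PlacementConfig
) -> tuple[BinaryMask, SearchSpace]:
    if mode == "enhancing":
        if seg.core is None or seg.core.n_voxels == 0:
            raise ModeError("enhancing mode requires a nonempty core mask")
        target = seg.core
    elif mode == "flair_only":
        if seg.whole is None or seg.whole.n_voxels == 0:
            raise ModeError("FLAIR-only mode requires a nonempty whole mask")
        target = seg.whole
    else:
        raise ValueError(f"unknown mode {mode!r}")
    space = build_search_space(
        target,
        pad_mm=cfg.pad_mm,
        center_stride_mm=cfg.center_stride_mm,
        angle_step_deg=cfg.angle_step_deg,
        side_mm=cfg.side_mm,
    )
    return target, space


def optimize(
    seg: TumorSegmentation,
    cfg: Optional[PlacementConfig] = None,
    mode: Optional[str] = None,
) -> PlacementReport:
    """Exhaustively search the placement space for the optimal cube."""
    cfg = cfg or PlacementConfig()
    _require_scoring_grid(seg)
    mode = mode or select_mode(seg, cfg.min_core_mm3)
    _, space = _space_for_mode(seg, mode, cfg)
    angles = space.angles()
    centers = space.centers()

    kq = max(100_000, int((cfg.side_mm + 2) ** 3) + 1)
    best_feas = None  # (key, center_idx, rot_idx)
    best_fall = None
    for ri in range(len(angles)):
        a = angles[ri]
        if mode == "enhancing":
            core_c = _rotation_counts(seg.core, a, space).reshape(-1)
            nec_c = (
                _rotation_counts(seg.necrosis, a, space).reshape(-1)
                if seg.necrosis is not None
                else np.zeros_like(core_c)
            )
            whole_c = (
                _rotation_counts(seg.whole, a, space).reshape(-1)
                if seg.whole is not None
                else np.zeros_like(core_c)
            )
            key_feas = np.where(nec_c == 0, core_c * kq + whole_c, -1)
            ci = int(np.argmax(key_feas))
            if key_feas[ci] >= 0 and (
                best_feas is None
                or key_feas[ci] > best_feas[0]
                or (key_feas[ci] == best_feas[0] and ci < best_feas[1])
            ):
                best_feas = (int(key_feas[ci]), ci, ri)
            key_fall = (kq - nec_c) * kq * kq + core_c * kq + whole_c
            cj = int(np.argmax(key_fall))
            if (
                best_fall is None
                or key_fall[cj] > best_fall[0]
                or (key_fall[cj] == best_fall[0] and cj < best_fall[1])
            ):
                best_fall = (int(key_fall[cj]), cj, ri)
        else:
            whole_c = _rotation_counts(seg.whole, a, space).reshape(-1)
            ci = int(np.argmax(whole_c))
            if (
                best_feas is None
                or whole_c[ci] > best_feas[0]
                or (whole_c[ci] == best_feas[0] and ci < best_feas[1])
            ):
                best_feas = (int(whole_c[ci]), ci, ri)

    fallback_used = False
    if best_feas is not None:
        _, ci, ri = best_feas
    else:
        if cfg.fallback == "forbid":
            raise InfeasibleError(
                "every candidate placement encloses necrosis and the "
                "fallback objective is forbidden"
            )
        fallback_used = True
        _, ci, ri = best_fall

    placement = CubePlacement(
        center_mm=centers[ci], angles_deg=angles[ri], side_mm=cfg.side_mm
    )
    return PlacementReport(
        placement=placement,
        score=score_placement(placement, seg),
        mode=mode,
        fallback_used=fallback_used,
        search=space.to_dict(),
        n_candidates_evaluated=space.n_candidates,
    )


def brute_force_oracle(
    seg: TumorSegmentation,
    cfg: Optional[PlacementConfig] = None,
    mode: Optional[str] = None,
) -> PlacementReport:
    """Literal per-candidate reference search (independent of the fast path).

    Loops over every candidate in iteration order, scores it with
    :func:`score_placement`, and applies the same objective and tie rules as
    :func:`optimize`.  Guarded to small candidate sets.
    """
    cfg = cfg or PlacementConfig()
    _require_scoring_grid(seg)
    mode = mode or select_mode(seg, cfg.min_core_mm3)
    _, space = _space_for_mode(seg, mode, cfg)
    if space.n_candidates > ORACLE_GUARD:
        raise ValueError(
            f"candidate set ({space.n_candidates}) exceeds the oracle guard "
            f"({ORACLE_GUARD})"
        )
    angles = space.angles()
    centers = space.centers()

    best_feas = None  # (objective tuple, center_idx, rot_idx, score)
    best_fall = None
    for ci, c in enumerate(centers):
        for ri, a in enumerate(angles):
            s = score_placement(
                CubePlacement(center_mm=c, angles_deg=a, side_mm=cfg.side_mm),
                seg,
            )
            if mode == "enhancing":
                if s.necrosis_mm3 == 0:
                    key = (s.core_mm3, s.whole_mm3)
                    if best_feas is None or key > best_feas[0]:
                        best_feas = (key, ci, ri, s)
                key = (-s.necrosis_mm3, s.core_mm3, s.whole_mm3)
                if best_fall is None or key > best_fall[0]:
                    best_fall = (key, ci, ri, s)
            else:
                key = (s.whole_mm3,)
                if best_feas is None or key > best_feas[0]:
                    best_feas = (key, ci, ri, s)

    fallback_used = False
    if best_feas is not None:
        _, ci, ri, s = best_feas
    else:
        if cfg.fallback == "forbid":
            raise InfeasibleError(
                "every candidate placement encloses necrosis and the "
                "fallback objective is forbidden"
            )
        fallback_used = True
        _, ci, ri, s = best_fall

    placement = CubePlacement(
        center_mm=centers[ci], angles_deg=angles[ri], side_mm=cfg.side_mm
    )
    return PlacementReport(
        placement=placement,
        score=s,
        mode=mode,
        fallback_used=fallback_used,
        search=space.to_dict(),
        n_candidates_evaluated=space.n_candidates,
    )


# ---------------------------------------------------------------------------
# heatmaps


def generate_heatmap(
    seg: TumorSegmentation,
    rotation_deg=(0.0, 0.0, 0.0),
    cfg: Optional[PlacementConfig] = None,
    mode: Optional[str] = None,
) -> Heatmap:
    """Enclosed-target-volume map over candidate centers at a fixed rotation.

    In enhancing mode, positions whose cube would enclose necrosis are marked
    invalid (left uncolored when rendered); the maximum over valid cells
    equals the best primary objective of :func:`optimize` restricted to this
    rotation.
    """
    cfg = cfg or PlacementConfig()
    _require_scoring_grid(seg)
    mode = mode or select_mode(seg, cfg.min_core_mm3)
    _, space = _space_for_mode(seg, mode, cfg)
    rotation_deg = np.asarray(rotation_deg, dtype=float).reshape(3)
    if mode == "enhancing":
        target_name = "core"
        values = _rotation_counts(seg.core, rotation_deg, space)
        valid = np.ones(values.shape, dtype=bool)
        if seg.necrosis is not None:
            nec = _rotation_counts(seg.necrosis, rotation_deg, space)
            valid &= nec == 0
    else:
        target_name = "whole"
        values = _rotation_counts(seg.whole, rotation_deg, space)
        valid = np.ones(values.shape, dtype=bool)
    return Heatmap(
        values=values.astype(np.float64),
        valid=valid,
        rotation_deg=rotation_deg,
        target=target_name,
        center_axes=space.center_axes,
        side_mm=space.side_mm,
    )


def export_heatmap(
    heatmap: Heatmap,
    reference: ImageVolume,
    path,
    midslice_path=None,
):
    """Write the heatmap as a NIfTI volume on the reference grid.

    Each reference voxel takes the value of its nearest candidate-lattice
    cell (nearest-neighbor); invalid cells and voxels outside the lattice map
    to NaN.  Optionally also writes a 2D mid-axial-slice raster for review.
    """
    import nibabel as nib

    if not reference.is_axis_aligned():
        raise ValueError("heatmap export requires an axis-aligned reference")
    vals = np.where(heatmap.valid, heatmap.values, np.nan)
    out = np.full(reference.shape, np.nan, dtype=np.float32)
    idx_ax, ok_ax = [], []
    for d in range(3):
        axis = heatmap.center_axes[d]
        world = reference.origin[d] + np.arange(reference.shape[d]) * reference.spacing[d]
        if len(axis) > 1:
            step = axis[1] - axis[0]
        else:
            step = max(1.0, heatmap.side_mm)
        k = np.rint((world - axis[0]) / step).astype(int)
        ok = (k >= 0) & (k < len(axis))
        ok &= np.abs(world - axis[0] - np.clip(k, 0, len(axis) - 1) * step) <= step / 2 + 1e-9
        idx_ax.append(k[ok])
        ok_ax.append(np.flatnonzero(ok))
    if all(len(i) for i in idx_ax):
        out[np.ix_(*ok_ax)] = vals[np.ix_(*idx_ax)].astype(np.float32)
    img = nib.Nifti1Image(out, reference.affine)
    nib.save(img, str(path))

    if midslice_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        mid = reference.shape[2] // 2
        fig, ax = plt.subplots(figsize=(5, 5))
        im = ax.imshow(out[:, :, mid].T, origin="lower", cmap="inferno")
        ax.set_title(
            f"enclosed {heatmap.target} volume (mm^3), "
            f"rot={tuple(heatmap.rotation_deg)}"
        )
        ax.set_xlabel("x (R+)")
        ax.set_ylabel("y (A+)")
        fig.colorbar(im, ax=ax, shrink=0.8)
        fig.savefig(midslice_path, dpi=100, bbox_inches="tight")
        plt.close(fig)
    return path
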