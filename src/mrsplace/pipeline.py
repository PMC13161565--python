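"""End-to-end orchestration: files in, cube mask + report + heatmap out."""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import io as mio
from .geometry import rasterize_cube
from .optimize import (
    PlacementConfig,
    PlacementReport,
    export_heatmap,
    generate_heatmap,
    optimize,
)
from .preprocess import to_common_grid

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one placement run needs.

    At least (t1c + core) or (flair + whole) must be supplied; the rest is
    optional per mode.  Search keys mirror :class:`PlacementConfig`.
    """

    t1c: Optional[Path] = None
    flair: Optional[Path] = None
    core: Optional[Path] = None
    necrosis: Optional[Path] = None
    whole: Optional[Path] = None
    out_dir: Path = Path("mrsplace_out")
    target_spacing_mm: float = 1.0
    assume_registered: bool = False
    allow_identity_fallback: bool = False
    placement: PlacementConfig = field(default_factory=PlacementConfig)

    def validate(self) -> None:
        ok_enh = self.t1c is not None and self.core is not None
        ok_flair = self.flair is not None and self.whole is not None
        if not (ok_enh or ok_flair):
            raise ValueError(
                "need at least (--t1c and --core) or (--flair and --whole)"
            )

    def to_dict(self) -> dict:
        return {
            "inputs": {
                k: (str(getattr(self, k)) if getattr(self, k) else None)
                for k in ("t1c", "flair", "core", "necrosis", "whole")
            },
            "out_dir": str(self.out_dir),
            "target_spacing_mm": self.target_spacing_mm,
            "assume_registered": self.assume_registered,
            "allow_identity_fallback": self.allow_identity_fallback,
            "placement": self.placement.to_dict(),
        }


def run_placement(cfg: RunConfig) -> tuple[PlacementReport, dict[str, Path]]:
    """Run the full pipeline and write all artifacts into ``cfg.out_dir``.

    Artifacts: one cube-mask NIfTI per supplied anatomical sequence, the
    placement report JSON (with a config echo sufficient to reproduce the
    run), and optionally the heatmap NIfTI plus a mid-slice PNG.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.time()

    t1c = mio.read_volume(cfg.t1c) if cfg.t1c else None
    flair = mio.read_volume(cfg.flair) if cfg.flair else None
    mask_anchor = t1c if t1c is not None else flair
    core = mio.read_mask(cfg.core, t1c) if cfg.core else None
    necrosis = mio.read_mask(cfg.necrosis, t1c) if cfg.necrosis else None
    whole = (
        mio.read_mask(cfg.whole, flair if flair is not None else mask_anchor)
        if cfg.whole
        else None
    )

    reference, seg = to_common_grid(
        t1c=t1c,
        flair=flair,
        core=core,
        necrosis=necrosis,
        whole=whole,
        target_spacing_mm=cfg.target_spacing_mm,
        assume_registered=cfg.assume_registered,
        allow_identity_fallback=cfg.allow_identity_fallback,
    )

    report = optimize(seg, cfg.placement)
    report.search["config_echo"] = cfg.to_dict()
    log.info(
        "mode=%s fallback=%s n_candidates=%d elapsed=%.1fs",
        report.mode,
        report.fallback_used,
        report.n_candidates_evaluated,
        time.time() - t_start,
    )

    artifacts: dict[str, Path] = {}
    cube = rasterize_cube(report.placement, reference)
    if cfg.t1c:
        artifacts["cube_mask_t1c"] = mio.write_mask(cube, out / "cube_mask_t1c.nii.gz")
    if cfg.flair:
        artifacts["cube_mask_flair"] = mio.write_mask(
            cube, out / "cube_mask_flair.nii.gz"
        )
    artifacts["report"] = mio.write_report(report, out / "placement_report.json")

    if cfg.placement.heatmap != "off":
        rot = (
            report.placement.angles_deg
            if cfg.placement.heatmap == "optimal"
            else np.zeros(3)
        )
        hm = generate_heatmap(seg, rot, cfg.placement, mode=report.mode)
        artifacts["heatmap"] = Path(
            export_heatmap(
                hm,
                reference,
                out / "heatmap.nii.gz",
                midslice_path=out / "heatmap_midslice.png",
            )
        )
        artifacts["heatmap_midslice"] = out / "heatmap_midslice.png"
    return report, artifacts


def validate_artifacts(
    report_path: Path,
    *,
    core: Optional[Path] = None,
    necrosis: Optional[Path] = None,
    whole: Optional[Path] = None,
) -> list[str]:
    """Re-score a reported placement from mask files; return mismatch diffs.

    The masks must already be on the common scoring grid (as written by the
    pipeline or the phantom generator).  Re-scoring depends only on the
    placement, not on the search stride, so artifacts regenerated at another
    stride still validate.
    """
    from .geometry import TumorSegmentation, score_placement

    report = mio.parse_report(report_path)
    paths = {"core": core, "necrosis": necrosis, "whole": whole}
    first = next(p for p in paths.values() if p is not None)
    reference = mio.read_volume(first)
    masks = {
        name: (mio.read_mask(p, reference) if p is not None else None)
        for name, p in paths.items()
    }
    seg = TumorSegmentation(**masks)
    score = score_placement(report.placement, seg)

    diffs = []
    for fld in ("core_mm3", "necrosis_mm3", "whole_mm3"):
        got = getattr(score, fld)
        exp = getattr(report.score, fld)
        if paths[fld.removesuffix("_mm3")] is None:
            continue
        if got != exp:
            diffs.append(f"{fld}: report={exp} recomputed={got}")
    if not report.fallback_used and necrosis is not None and score.necrosis_mm3 != 0:
        diffs.append(
            "non-fallback placement encloses necrosis "
            f"({score.necrosis_mm3} mm^3)"
        )
    return diffs
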