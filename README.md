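# mrsplace

Automated placement of the single-voxel MRS acquisition cube for brain tumor
imaging.

Single-voxel MR spectroscopy samples metabolite signal from one cuboidal
volume — in routine practice a fixed 2 × 2 × 2 cm³ cube positioned by hand on
anatomical images, under time pressure, with considerable inter-operator
variability. Given post-contrast T1 (T1C+) and/or T2-FLAIR volumes plus
binary tumor sub-compartment masks (enhancing core and necrosis on T1C+,
whole FLAIR-hyperintense tumor on FLAIR), `mrsplace` searches rigid poses of
the cube and returns the one that maximizes enclosed enhancing tumor while
enclosing **zero necrosis** (necrotic tissue corrupts the spectrum), with
whole-tumor coverage as tiebreaker. For non-enhancing lesions it maximizes
enclosed FLAIR-hyperintense volume instead. Segmentation masks are inputs;
this package does not produce them.

It is aimed at researchers prototyping spectroscopy planning workflows and
needing a reproducible, auditable placement: results are deterministic,
scores are exact voxel counts, and every reported placement can be re-scored
from the artifacts.

## Method in brief

All inputs are brought onto a common 1 mm isotropic RAS grid (FLAIR rigidly
co-registered onto T1C+ when both are present). For a cube of side
*s* = 20 mm at center **c** with rotation
R = R_z(a_z)·R_y(a_y)·R_x(a_x), a_i ∈ [0°, 90°], the enclosed volume of a
mask is

&nbsp;&nbsp;&nbsp;&nbsp;V(p) = #{ voxel centers x : Rᵀ(x − c) ∈ [−s/2, s/2)³ } · 1 mm³

The search enumerates cube centers on a stride lattice inside the target's
bounding box padded by 2√3 cm per side (the limit for the cube *center*),
restricted to poses that fit the image, and angle triples on
{0, step, …, 90}³. Objective, lexicographic: feasible placements
(necrosis count 0) ranked by (core, whole); FLAIR-only mode ranks by whole
alone. A flagged fallback (minimize necrosis, then maximize core) handles
lesions where no necrosis-free cube exists. Enclosed-volume maps
("heatmaps") over all candidate centers make the optimum visually auditable.
See `docs/methods.md` for the full account.

## Worked example

Generate a synthetic enhancing tumor phantom and place the cube:

```bash
mrsplace phantom small_enhancing --out ph --seed 7
mrsplace place \
    --t1c ph/small_enhancing_00_t1c.nii.gz \
    --flair ph/small_enhancing_00_flair.nii.gz \
    --core ph/small_enhancing_00_core.nii.gz \
    --necrosis ph/small_enhancing_00_necrosis.nii.gz \
    --whole ph/small_enhancing_00_whole.nii.gz \
    --out run --stride 4 --angle-step 45 --assume-registered
```

which prints (abridged):

```json
{
  "mode": "enhancing",
  "fallback_used": false,
  "center_mm": [64.0, 64.0, 64.0],
  "angles_deg": [0.0, 0.0, 45.0],
  "score": { "core_mm3": 2109, "necrosis_mm3": 0, "whole_mm3": 7956, "feasible": true }
}
```

Reading: the optimal cube sits at world center (64, 64, 64) mm, rotated 45°
about the superior/inferior axis;
it encloses the phantom's entire 2109 mm³ enhancing core (the core fits
inside the 8000 mm³ cube, so full enclosure is attainable and achieved),
zero necrosis, and 7956 mm³ of surrounding FLAIR-hyperintense tissue — the
tiebreaker that picked this center among all fully-enclosing ones. The run
directory contains the cube rasterized as a NIfTI mask on each input
sequence, `placement_report.json` (pose, scores, full search parameters —
re-scorable with `mrsplace validate`), and the heatmap volume plus a
mid-slice PNG.

Library use mirrors the CLI:

```python
from mrsplace import optimize, PlacementConfig
from mrsplace.phantom import phantom_suite, generate_phantom

_, _, seg = generate_phantom(phantom_suite("small_enhancing")[0])
report = optimize(seg, PlacementConfig(center_stride_mm=4, angle_step_deg=45))
print(report.score.core_mm3, report.placement.center_mm)
```

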