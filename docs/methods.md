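# Methods

## Problem and model

Single-voxel MR spectroscopy (MRS) samples metabolite signal from one cuboidal
acquisition volume, in routine practice a fixed 2 × 2 × 2 cm³ cube placed by
hand on anatomical images. Placement quality determines spectral quality:
the cube should cover as much viable (contrast-enhancing) tumor as possible,
and necrotic tissue inside the cube corrupts the spectrum. `mrsplace`
automates this placement given anatomical volumes and binary sub-compartment
segmentations (enhancing core and necrosis on post-contrast T1, whole
FLAIR-hyperintense tumor on FLAIR). Segmentations are *inputs*; producing
them (e.g. with a deep segmentation model) is out of scope.

The placement is a rigid pose of a cube of side `s` (default 20 mm):
a world-space center `c` and extrinsic rotations `(a_x, a_y, a_z)` about the
patient left/right, anterior/posterior and superior/inferior axes, composed
as `R = R_z(a_z) · R_y(a_y) · R_x(a_x)`, each angle in [0°, 90°]. Rotation is
about the cube center. Because the cube has full octahedral symmetry, the
[0, 90]³ angle range already covers a rich set of orientations; the
composition order is a convention this package fixes (the pose parameters are
reported with it).

### Objective

All masks live on a common 1 mm isotropic RAS-aligned grid. For a placement
`p`, the enclosed volume of a mask is the number of its nonzero grid-voxel
*centers* `x` with `q = Rᵀ(x − c) ∈ [−s/2, s/2)³`, times 1 mm³.

- **Enhancing mode** (core volume ≥ `min_core_mm3`, default 100 mm³):
  restrict to *feasible* placements (zero enclosed necrosis), maximize the
  lexicographic key (enclosed core, enclosed whole tumor). The whole-tumor
  term is a tiebreaker: among equally core-covering cubes, prefer more
  peritumoral signal.
- **FLAIR-only mode** (no/negligible enhancement, typical of low-grade
  gliomas): maximize enclosed whole-tumor volume; registration to T1C+ is
  skipped and the grid anchors to FLAIR.
- **Fallback** (no feasible placement exists anywhere): maximize
  (−necrosis, core, whole) and set `fallback_used` — the clinical user still
  needs a proposal, but the flag is loud. This situation is an edge case the
  underlying workflow never addresses; forbidding the fallback turns it into
  a distinct nonzero exit code.

Residual ties are broken by the earliest candidate in a fixed iteration
order (centers ascending by (x, y, z), then angle triples ascending), so
results are bitwise reproducible.

### Search space

A bounding box is drawn around the target mask (core in enhancing mode,
whole tumor otherwise) and padded by 2√3 cm = 34.6410… mm per side; that box
limits the cube *center*. The pad constant is kept at full floating
precision. Within the box, candidate centers form a lattice
`mid + k · stride, k ∈ [−m, m]` centered on the box midpoint with an odd
point count per axis. This construction has two properties the search's
invariants rely on:

- halving the stride yields a superset lattice (refinement can only improve
  the optimum), and
- the lattice maps onto itself under the grid's 90° lattice symmetries.

Centers where the cube's circumscribing sphere (radius `s·√3/2`) would leave
the image field of view are discarded. Candidate angles per axis are
`{0, step, 2·step, …}` with 90° always included (default step 15°, i.e. 343
rotations; the search density is this package's choice — the workflow it
automates does not pin one down).

## Exact counting, twice

Two independent routes compute enclosed volumes, and the test suite holds
them to *integer equality*:

1. `score_placement` — per-placement counting over the mask's nonzero voxel
   coordinates (a numba-compiled branchless loop, with a numpy fallback).
   The brute-force reference search (`brute_force_oracle`) is a literal loop
   over every candidate calling this scorer.
2. The production search (`optimize`) — for each rotation, enclosed counts
   for *all* centers at once as a cross-correlation of the mask with a cube
   membership kernel rasterized on the offset lattice, evaluated by FFT.
   FFT round-off (≪ 0.5 on counts ≤ 8000) is removed by rounding; for
   non-integer strides the offsets do not form a lattice and a direct
   per-candidate path is used instead.

Cube membership is **half-open** (`[−s/2, s/2)` per axis): an axis-aligned
cube at an integer center encloses exactly 20³ = 8000 voxels and opposite
faces never double-count. Both bounds are shifted inward by 1e−6 mm so that
exact boundary ties — which genuinely occur, since centers lie on rational
lattices — are decided identically by every code path regardless of
floating-point summation order; no non-tie voxel can be reclassified because
true center-to-face distances on these lattices are never below ~0.25 mm.
Scoring is binary per voxel center (no partial-volume fractions): at 1 mm
resolution the sub-voxel error is negligible against a 8000 mm³ cube, and
exactness is what makes the dual-route check meaningful.

## Preprocessing

Images are resampled to an axis-aligned 1 mm isotropic RAS grid (linear for
intensities, nearest-neighbor for masks — binarity and count-based volumes
must survive). The output voxel-center lattice stays inside the input
extent, sacrificing at most one edge voxel of field of view. In enhancing
mode FLAIR is rigidly co-registered onto the T1C+ grid (6 DOF, SimpleITK,
Mattes mutual information, full sampling, multi-resolution gradient
descent); the whole-tumor mask is warped with the resulting transform,
nearest-neighbor. A pass-through mode accepts precomputed/identity
transforms (`assume_registered`).

The registration contract is checked by metric comparison on lightly
smoothed copies of the images (σ = 1 mm), with a 5% relative tolerance:
with noisy inputs, sub-voxel resampling of an already-aligned pair blurs the
noise and lowers raw-image MI even when alignment is ideal, while true
divergence moves the metric far beyond a few percent. Failure raises unless
an identity fallback is explicitly permitted.

## Synthetic phantoms

The generator emulates only what the optimizer consumes: nested ellipsoids
(necrosis ⊆ core ⊆ edema, mutually exclusive core/necrosis labels) with
fixed intensity levels (background 0, edema 60, core 100, necrosis 20,
arbitrary units) plus additive Gaussian noise under a fixed seed. Ellipsoids
make optimal placements geometrically interpretable and give closed-form
volumes to converge to; they do not model MR physics, contrast kinetics,
lesion texture, or mass effect — so passing tests demonstrate the geometry
and search are right, not that segmentations of real tumors will be.

The five phantom families cover the algorithm's branch structure: a small
enhancing core (full enclosure attainable, tiebreaker active), a rotated
anisotropic core with interior necrosis (constraint active), a non-enhancing
lesion (FLAIR-only), a core larger than the cube (partial enclosure), and a
case whose necrosis covers every admissible cube (fallback). The last family
lives on a 48³ grid: under the nesting invariant, necrosis must scale with
the padded search space to cover all candidates, and the smaller domain
keeps the exhaustive brute-force verification of "no feasible cube exists"
tractable. The other families use 128³ grids.

## Verification problem sizes

The exhaustive-equivalence check (production search vs brute-force loop)
runs all five families at 4 mm stride and 30° angle step — 0.6–0.8 million
candidate placements per phantom — and demands integer-exact agreement in
placement, score and fallback flag. The zero-necrosis guarantee is checked
on 100 randomized necrotic phantoms (64³, stride 4 mm, step 45°).
Refinement monotonicity is checked by halving stride (8→4 mm) and angle step
(60°→30°).

The 90° lattice-rotation symmetry of the optimum is checked at the {0, 90}
angle grid. A finite Euler-angle grid is generally *not* closed (modulo the
cube's rotation group) under a 90° axis relabeling — numerically, 12 of 64
orientations at 30° step have no equivalent grid orientation after the
rotation — so exact symmetry of the discrete optimum can only be demanded
when the orientation set is closed, as it is for {0, 90}³ (a subset of the
cube group). With finer angle grids the property holds approximately but not
integer-exactly.

## Heatmaps

For a fixed rotation, the enclosed-target volume at every candidate center
is exported as a map over the center lattice: cells whose cube would enclose
necrosis, or that fall outside the search space, are invalid (rendered
uncolored / NaN). The maximum over valid cells equals the best primary
objective of the search restricted to that rotation — a direct visual audit
of the optimizer. Default rendering rotation is identity, optionally the
optimizer's chosen rotation.

## Known limitations

- Avoidance of other spectrum-degrading structures (ventricles, calvarium,
  resection cavities) is not modeled.
- Fixed cubic volume; anisotropic or multi-voxel acquisitions are out of
  scope.
- Voxel-center counting ignores partial volumes at the cube faces
  (≤ a few percent of the cube at 1 mm resolution).
- Registration quality is only as good as intensity-based rigid MI on the
  supplied contrasts; the phantom suite exercises translation recovery, not
  pathology-driven misalignment.
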