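# Methods

This note records the models, algorithms, parameter choices and known
limitations behind `airtree`.  Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`.

## Coordinate and data conventions

All grids are `(z, y, x)`, slices first, 0-based; world coordinates are
millimetres with `world = origin + index · spacing` per axis.  Direction
cosines are not supported: the tool targets axis-aligned thoracic
acquisitions (typically 0.5 mm slice increment, occasionally coarser).
MetaImage support covers MET_SHORT / MET_UCHAR / MET_FLOAT, uncompressed,
little-endian by default (the header's byte-order flag is honoured on
read).  Centerline trees are exchanged as VTK legacy ASCII polydata — one
polyline per branch, junction points stored once and shared by index, and
a `generation` point-data scalar.  On reading, a tree is re-rooted at the
maximal-z polyline endpoint (the cranial end of the trachea) and
generations are recomputed from topology, so round trips preserve geometry
to ≤ 1e-4 mm and branch topology exactly.

## The phantom

The phantom stands in for patient CT and supplies exact ground truth.  It
is a dichotomous tree of capsules (cylinders with hemispherical caps): a
vertical trachea splits at the carina into two main bronchi; each child is
rotated ±35° from its parent, in planes alternating between generations so
consecutive bifurcations are roughly orthogonal, as in real lungs.  Radius
and length taper geometrically (defaults: 9 mm and 30 mm at the trachea,
factor 0.7 per generation), which puts generation 5 at 2.2 mm radius —
small-bronchus calibre, consistent with reported adult airway diameters of
a few millimetres.  Tissue model: lumen −1000 HU inside a 1.5 mm wall at
0 HU, embedded in parenchyma at −850 HU, plus optional i.i.d. Gaussian
noise (20 HU in the noisy study conditions).  Defaults use 0.5 mm
isotropic voxels; a spec whose deepest generation falls below twice the
voxel spacing is rejected as unresolvable, and the rendered bounding box
is capped at 256³ voxels.

Ground truth shipped with each phantom: the exact lumen mask; the
centerline tree sampled along each branch axis at ≤ spacing/2; reference
labels in the EXACT09 style (correct = lumen, unknown = a one-voxel rind
around the lumen, wrong = everything else) with a per-voxel branch id
(nearest branch by signed distance `d − r`, so each branch owns its axis
territory beyond the parent's bulb) and trachea / main-bronchus sub-masks.
`corrupt_segmentation` manufactures known-imperfect inputs for metric
tests: it drops all branches above a chosen generation and attaches
26-connected leak blobs of an exact voxel count in the wrong-labelled
region, mutually separated so each is its own leakage component.
`punch_wall_hole` opens an air path through one wall to reproduce the
leakage failure mode of threshold growing.

What the phantom does **not** emulate: parenchymal texture and vasculature,
cartilage rings, partial-volume blur at the wall (the lumen/wall boundary
is a hard step), breathing/cardiac motion, tumours or mucus plugging.
Passing on phantoms therefore demonstrates the correctness of the
geometry, topology and bookkeeping of every stage under controlled
contrast and noise — not clinical-grade robustness on pathological lungs.

## Automatic cropping

Voxels below −500 HU are air-like (lumen and parenchyma).  6-connected
air components touching a *lateral* image border are body-exterior air and
are discarded; the bounding box of the remaining air, padded by 2 voxels,
is the crop.  The crop stores its voxel offset, and the cropped volume
keeps a world origin consistent with the parent grid, so masks embed back
exactly and centerlines need no remapping.

## Tube detection filter

A multi-scale Hessian filter for *dark* tubes.  Per scale r the volume is
smoothed with σ = r/√2 (near-optimal for a cylinder of radius r; per-axis
σ in voxels handles anisotropic spacing), the Hessian is γ-normalised with
γ = 2 (multiplied by σ² in mm²), and its eigenvalues are taken in **value
order** λa ≤ λb ≤ λc via a vectorised closed-form (trigonometric) solver.
The response for λb > 0 is

    V = exp(−(min(λa,0)/λc)²/2β²) · (1 − exp(−(λb/λc)²/2α²)) · (1 − exp(−S²/2c²)),

with α = 0.5, β = 0.25, S = ‖λ‖₂ and c = contrast/2 (contrast default
100 HU, the lumen/parenchyma scale of lung CT).  Design notes:

- **Value ordering, not magnitude ordering.**  The classical vesselness
  sorts by |λ|, which is discontinuous where |λa| = |λb| with opposite
  signs; on symmetric inputs this produced voxel-level instability.  Value
  ordering with the explicit saddle penalty (first factor, suppressing
  bright-ridge-through-dark-plane structures) is continuous everywhere.
- **No blob suppression.**  Bifurcations look blob-like; suppressing them
  disconnects the thresholded airway component at every carina.  Junction
  responses are therefore kept high by design.
- **Exact offset invariance.**  Truncated Gaussian-derivative kernels do
  not annihilate constants exactly, so the volume mean is subtracted
  before filtering; the map is then exactly invariant under a global HU
  shift and exactly zero on constant volumes (maps whose peak response is
  below 1e-6 are zeroed rather than rescaled).
- Boundary handling is nearest-neighbour extension; mirrored (reflect)
  padding fabricates bright wall images just outside tight crops, which
  produced spurious strong tube responses at crop corners.
- The per-voxel score is the max over scales, divided by the global max,
  giving values in [0, 1] with max exactly 1 whenever any structure
  responds.

Scales default to {1.5, 2, 3, 4.5, 6, 9} mm, spanning trachea to
6th-generation radii; each scale must be at least the voxel spacing.

## Centerline extraction

Voxels at or above the probability threshold (default 0.15) are selected
and the 26-connected component containing the global response maximum —
the dominant tube, in practice the trachea — is kept.  Choosing the
peak's component rather than the largest component makes the stage robust
against large agglomerations of weak off-airway responses.  The component
is *solidified* (morphological closing, then 3-D hole filling plus
per-slice 2-D hole filling along each axis): scale-space interference
leaves one-voxel gaps, and the response dips at the centre of tube ends,
leaving ring cross-sections whose skeleton would be a loop.  The solid
component is skeletonized with Lee's topology-preserving 3-D thinning;
skeleton voxels become a graph with 26-neighbour edges weighted by
Euclidean mm distance, a minimum spanning tree removes residual loops
deterministically, and the tree is rooted at the maximal-z degree-1 node
(ties broken in raster order).  Terminal spurs shorter than the prune
length (preset 4 mm; API default 2 × mean spacing) are removed
iteratively, pass-through junctions are dissolved, and generations are
recomputed — the operation is idempotent.  Finally the root start and
every terminal tip are extended along the local branch direction while
the distance-to-boundary (EDT) profile stays flat, recovering the length
that thinning erodes at tube ends without overshooting into the rounded
caps (the march stops when depth falls at more than half unit rate from
its running maximum, with half-voxel slack).  Junctions with more than two
children are kept as-is: all children get the parent generation + 1, and
no artificial short branches are invented at trifurcation-like points.

The same skeleton machinery serves `thinning_centerline`, which operates
on a binary mask directly (used for segmentations imported from
threshold-based tools that provide no probability map).

## Segmentation from the centerline

Seeds are all voxels within the dilation radius (default 1 mm) of any
centerline point (Euclidean distance transform, mm-scaled).  With the
gradient factor set to 0 growth is disabled and the seeds are returned.
Otherwise a candidate voxel is accepted iff

1. its HU is below `min(hu_ceiling, Q99(seed HU) + 75 HU)` — the ceiling
   (default −500 HU) bounds growth to air-like tissue, and the adaptive
   term anchors it to the seed (lumen) intensity distribution, which is
   what stops growth through wall defects into the brighter parenchyma;
2. its gradient magnitude (central differences, mm-scaled) is below
   `gradient_factor ×` the wall gradient, estimated as the 95th percentile
   of gradient magnitudes on the boundary of the intensity-connected
   region reachable from the seeds.

The output is the union of the seeds with all accepted voxels 26-connected
to them (computed as connected components of the acceptance mask, which is
equivalent to FIFO growth with a static predicate and deterministic).  A
note on the gradient gate: calibrating on the *seed-set* boundary alone is
degenerate on clean data — deep inside a noise-free lumen the gradient is
exactly zero — so the wall estimate uses the reachable region's boundary,
which actually lies at the wall.  On a noise-free phantom the result
equals the exact lumen (Dice 1.0); through a punched wall hole its leakage
volume is orders of magnitude below threshold growing's, which floods the
parenchyma (both measured in the comparative leakage test).

Threshold-interval growing (`region_grow_threshold`) is provided as the
comparator: the connected component of the HU-interval mask containing the
seed, 26-connected by default, with the classic −990 … −120 HU airway
interval as preset bounds.

## Evaluation formulas

Against reference labels (correct / wrong / unknown + branch ids):

- `overlap_counts`: Nc, Nw = segmented voxels on correct resp. wrong
  regions; unknown voxels count in neither; trachea and main-bronchus
  voxels are excluded (these counts exist solely to feed the
  false-positive rate, for which both exclusions are prescribed).
- `false_positive_rate` = Nw/(Nc+Nw) × 100; an error if the segmentation
  is empty after exclusions.
- `branch_detection`: a reference branch is detected iff ≥ 1 candidate
  centerline point lands in a voxel with that branch's id; the trachea is
  excluded from Nseg and Nref.  The matching tolerance is deliberately
  zero extra voxels: the branch-id field already extends to the full lumen
  radius.
- `tree_length_detected`: measured along the *reference* centerline —
  a segment counts when both endpoints lie in segmented voxels — so
  Lseg ≤ Lref by construction; trachea excluded; reported in cm.
- `leakage_stats`: 26-connected components of wrong-labelled segmented
  voxels (count) and their total volume in mm³; unknown is never leakage.
  Main-bronchus voxels are correct-labelled and thus cannot be leakage;
  no further exclusion is applied to leakage.
- Disconnected-but-correct fragments count toward all measures (the
  candidate mask is not required to be a single component).

A brute-force per-voxel/per-point reimplementation of all five formulas
lives in the test suite and must agree exactly on randomized small grids.

## Pipeline, presets, determinism

`run_pipeline` chains crop → TDF → centerline → segmentation, logs every
stage's parameters and wall-clock time, and returns the mask embedded in
the original grid plus per-generation metrics.  Parameters come from named
presets in a plain-text key=value file (`lung-airways` for patient-scale
CT, `lung-airways-phantom` for the synthetic conditions; they currently
share values).  Every stage is deterministic — fixed tie-breaks, no
randomness — so a fixed input and preset reproduce bit-identical outputs;
phantom generation is deterministic given its seed.

## Problem sizes and test conditions

The test suite and acceptance script use phantoms of 1–5 generations
(volumes up to roughly 220 × 150 × 150 voxels at 0.5 mm), noise-free and
at 20 HU, chosen to exercise trachea-to-subsegmental scale spans while
keeping a full suite run around a minute or two on one CPU.  The
acceptance script reports means over 3-, 4- and 5-generation noisy
phantoms with seeds derived from `--seed`.

## Known limitations

- The gradient gate is calibrated per volume from the reachable-region
  boundary; on volumes with no wall-like boundary at all the 95th
  percentile reflects noise and the gate degenerates to the intensity
  criterion.
- Branch detection credits a branch from a single centerline point; with
  a matching tolerance of zero this is conservative only because branch
  ids tile the full lumen.
- Anatomical branch naming, DICOM import, compressed MetaImage, direction
  cosines and GPU execution are out of scope.
- Generation counting assumes a rooted tree; rings (which real airways do
  not have, but imperfect skeletons can) are broken by the MST before
  decomposition, so a loop's second arm appears as an extra branch rather
  than an error.
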