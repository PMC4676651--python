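# airtree

Automatic airway-tree segmentation, centerline extraction and quantitative
evaluation for thoracic CT — with a synthetic phantom generator that makes
the whole pipeline testable without patient data.

Segmenting the bronchial tree from CT is a standard preprocessing step for
navigated bronchoscopy and airway quantification.  Classic threshold-based
region growing (flood-fill over an HU interval such as −990 … −120) is
simple but *leaks* into the lung parenchyma wherever the thin airway wall
is broken by noise, because lumen (≈ −1000 HU) and parenchyma (≈ −850 HU)
overlap in intensity.  `airtree` implements a centerline-first alternative:

1. **auto-crop** — discard everything outside the lung region (air-like
   voxels not connected to the lateral image border);
2. **tube detection filter (TDF)** — a multi-scale Hessian analysis giving
   every voxel a score in [0, 1] for lying inside a *dark* tube.  With
   value-ordered eigenvalues λa ≤ λb ≤ λc of the γ-normalised Hessian,

   V = exp(−(min(λa,0)/λc)² / 2β²) · (1 − e^{−(λb/λc)²/2α²}) · (1 − e^{−S²/2c²})  for λb > 0,

   where S = ‖λ‖₂; the score is the maximum over scales (default
   1.5–9 mm, trachea to 6th generation);
3. **centerline extraction** — threshold the map, keep the component with
   the strongest response, skeletonize (topology-preserving 3-D thinning),
   link the skeleton into a rooted tree (root = cranial trachea end), prune
   spurs, decompose into branches with generations (trachea = 1);
4. **segmentation** — seeded region growing from the dilated centerline,
   gated by an adaptive intensity ceiling and an image-gradient criterion
   calibrated on the detected wall gradient, which is what keeps leakage
   far below plain threshold growing;
5. **metrics & evaluation** — branch counts per generation, total
   centerline length (mm), segmented volume (voxels × voxel volume), and
   an EXACT09-style reference evaluation: branch detection
   `Nseg/Nref·100%`, tree-length detection `Lseg/Lref·100%`,
   false-positive rate `Nw/(Nc+Nw)·100%`, leakage count/volume, with the
   trachea excluded from all measures and the main bronchi additionally
   excluded from the false-positive rate.

Volumes travel as MetaImage (`.mhd`/`.raw`), centerlines as VTK legacy
ASCII polydata; both are read/written losslessly.

## Worked example

```python
import airtree
from airtree.pipeline import PipelineConfig, run_pipeline

# a 4-generation branching-airway phantom with exact ground truth
bundle = airtree.generate_phantom(
    airtree.PhantomSpec(generations=4, noise_sigma_hu=20.0, seed=7))

result = run_pipeline(bundle.volume, PipelineConfig(preset="lung-airways-phantom"))
print("branches per generation:", result.report["branches_per_generation"])
print("total length: %.1f mm" % result.report["total_length_mm"])

score = airtree.evaluate_segmentation(
    result.mask, result.tree, bundle.labels, bundle.tree)
print("branch detected: %.1f%%" % score.branch_detected_pct)
print("tree length detected: %.1f%%" % score.tree_length_pct)
print("false positive rate: %.2f%%" % score.false_positive_rate_pct)
```

prints

```
branches per generation: {'1': 1, '2': 2, '3': 4, '4': 8}
total length: 233.1 mm
branch detected: 100.0%
tree length detected: 100.0%
false positive rate: 0.00%
```

i.e. despite 20 HU of added noise the pipeline recovers the phantom's
exact branch histogram (1 trachea, 2 main bronchi, 4 lobar, 8 segmental
branches), every non-trachea branch and the full reference tree length,
with no voxel counted outside the true lumen.

The same stages are available from the shell:

```bash
airtree phantom --generations 4 --seed 7 --out ph/
airtree run ph/volume.mhd --preset lung-airways-phantom --out out/
airtree evaluate --seg out/segmentation.mhd --seg-tree out/centerline.vtk \
        --ref-bundle ph/ --out eval.json
```

(also `tdf`, `centerline`, `segment`, `grow`, `metrics` for the individual
stages; exit codes: 0 ok, 2 parameter error, 3 data error).

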