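"""Seeded region growing: threshold-interval and centerline-seeded variants.

``region_grow_threshold`` is the classic dynamic region growing used by
clinical packages: from a trachea seed, flood all connected voxels whose
HU lies in a user-chosen interval (typically −990 … −120 HU for airways).
Its known failure mode is leakage through thin or broken airway walls into
the parenchyma, whose HU overlaps the interval.

``segment_from_centerline`` is the pipeline's segmentation stage: the
already-extracted centerline is dilated into a seed tube, and growth from
it is doubly gated to limit leakage — by an intensity ceiling that adapts
to the seed intensities (air voxels), and by an image-gradient gate
calibrated on the gradient magnitude at the detected lumen boundary (the
airway wall).  Both variants are deterministic.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .core import BinaryMask, DataError, ParameterError, VolumeImage
from .tree import CenterlineTree

_B26 = np.ones((3, 3, 3), dtype=bool)
_B6 = ndimage.generate_binary_structure(3, 1)


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 6:
        return _B6
    if connectivity == 26:
        return _B26
    raise ParameterError("connectivity must be 6 or 26")


def region_grow_threshold(volume: VolumeImage, seed_voxel, lower_hu: float,
                          upper_hu: float, connectivity: int = 26) -> BinaryMask:
    """Flood fill from ``seed_voxel`` over voxels with HU in [lower, upper].

    Equivalent to a FIFO seeded region growing with a static acceptance
    interval: the result is the connected component of the threshold mask
    that contains the seed.
    """
    structure = _structure(connectivity)
    seed = tuple(int(i) for i in seed_voxel)
    if any(i < 0 or i >= s for i, s in zip(seed, volume.shape)):
        raise ParameterError(f"seed voxel {seed} outside the volume {volume.shape}")
    if lower_hu > upper_hu:
        raise ParameterError("lower_hu must not exceed upper_hu")
    hu = float(volume.data[seed])
    if not lower_hu <= hu <= upper_hu:
        raise DataError(
            f"seed not in threshold interval: HU {hu:.1f} outside [{lower_hu}, {upper_hu}]")
    inside = (volume.data >= lower_hu) & (volume.data <= upper_hu)
    lab, _ = ndimage.label(inside, structure=structure)
    return BinaryMask(lab == lab[seed], volume.spacing, volume.origin)


def segment_from_centerline(volume: VolumeImage, tree: CenterlineTree,
                            dilation_radius_mm: float = 1.0,
                            hu_ceiling: float = -500.0,
                            gradient_factor: float = 1.0,
                            intensity_margin_hu: float = 75.0,
                            connectivity: int = 26) -> BinaryMask:
    """Grow the airway lumen from the dilated centerline.

    Seeds are all voxels within ``dilation_radius_mm`` of any centerline
    point.  A candidate voxel is accepted iff

    * its HU is below ``min(hu_ceiling, Q99(seed HU) + intensity_margin_hu)``
      — the adaptive ceiling keeps growth in air-like voxels near the seed
      intensity and is what stops leakage through wall defects into the
      (brighter) parenchyma; and
    * its gradient magnitude (central differences, mm-scaled) is below
      ``gradient_factor`` × the wall gradient, estimated as the 95th
      percentile of gradient magnitudes on the boundary of the
      intensity-connected region reachable from the seeds.

    The result is the union of the seeds and the accepted voxels connected
    to them.  ``gradient_factor = 0`` disables growth entirely (seeds only).
    """
    if not tree.branches:
        raise DataError("empty centerline tree")
    if dilation_radius_mm < 0:
        raise ParameterError("dilation_radius_mm must be >= 0")
    structure = _structure(connectivity)
    spacing = np.asarray(volume.spacing)
    pts = tree.all_points()
    idx = volume.world_to_index(pts)
    ok = np.all((idx >= 0) & (idx < np.asarray(volume.shape)), axis=1)
    if not ok.any():
        raise DataError("no centerline point lies inside the volume")
    idx = idx[ok]
    pointmask = np.zeros(volume.shape, dtype=bool)
    pointmask[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    if dilation_radius_mm > 0:
        dist = ndimage.distance_transform_edt(~pointmask, sampling=spacing)
        seeds = dist <= dilation_radius_mm
    else:
        seeds = pointmask
    if gradient_factor == 0:
        return BinaryMask(seeds, volume.spacing, volume.origin)

    # adaptive intensity ceiling from the seed HU distribution
    seed_hu = volume.data[seeds]
    ceiling = min(float(hu_ceiling),
                  float(np.quantile(seed_hu, 0.99)) + float(intensity_margin_hu))
    dark = volume.data < ceiling

    # provisional intensity-connected region -> wall-gradient estimate
    lab, _ = ndimage.label(dark | seeds, structure=structure)
    seed_labels = np.unique(lab[seeds])
    seed_labels = seed_labels[seed_labels != 0]
    region0 = np.isin(lab, seed_labels)
    gz, gy, gx = np.gradient(volume.data.astype(np.float32),
                             spacing[0], spacing[1], spacing[2])
    gradmag = np.sqrt(gz * gz + gy * gy + gx * gx)
    boundary = region0 & ~ndimage.binary_erosion(region0, structure=_B6)
    wall_gradient = float(np.percentile(gradmag[boundary], 95)) if boundary.any() else 0.0

    allowed = dark & (gradmag <= gradient_factor * wall_gradient)
    lab, _ = ndimage.label(allowed | seeds, structure=structure)
    seed_labels = np.unique(lab[seeds])
    seed_labels = seed_labels[seed_labels != 0]
    out = np.isin(lab, seed_labels) & (allowed | seeds)
    out |= seeds
    return BinaryMask(out, volume.spacing, volume.origin)
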