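"""Automatic lung-region cropping and the multi-scale tube detection filter.

The tube detection filter (TDF) assigns every voxel a probability-like
score in [0, 1] of lying inside a dark tubular structure (air-filled
airway surrounded by brighter tissue).  It is a multi-scale Hessian
eigenvalue analysis: at each scale σ the volume is smoothed with a
Gaussian, the 3×3 Hessian is γ-normalised (γ = 2, i.e. multiplied by σ²)
and its value-ordered eigenvalues λa ≤ λb ≤ λc classify the local
structure.  A dark tube has both in-plane curvatures positive
(λb ≈ λc > 0) and λa small, so the response

    V = (1 − exp(−(λb/λc)² / 2α²)) · (1 − exp(−S² / 2c²)),   λb > 0

with S = sqrt(λa² + λb² + λc²) and α = 0.5 is large inside tubes and at
bifurcations (where λa also becomes positive) and small in homogeneous
tissue and on plates.  Value ordering (rather than the magnitude ordering
of the classical vesselness) keeps V continuous in the Hessian entries,
and no blob-suppression term is used: bifurcation voxels must stay above
threshold or the thresholded airway component would disconnect at every
carina.  The per-voxel score is the maximum over scales, rescaled to
[0, 1] by the global maximum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import BinaryMask, DataError, ParameterError, VolumeImage

DEFAULT_SCALES_MM = (1.5, 2.0, 3.0, 4.5, 6.0, 9.0)


@dataclass
class TubeProbabilityMap:
    """Per-voxel tube likelihood in [0, 1], aligned to its source volume."""

    data: np.ndarray
    radii_mm: tuple[float, ...]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]

    @property
    def shape(self):
        return self.data.shape


@dataclass
class CropResult:
    """A cropped volume plus the voxel offset locating it in the original grid."""

    volume: VolumeImage
    offset_voxels: tuple[int, int, int]

    def embed_mask(self, mask: BinaryMask, original_shape: tuple[int, int, int],
                   original_origin: tuple[float, float, float]) -> BinaryMask:
        """Place a mask defined on the cropped grid back into the full grid."""
        out = np.zeros(original_shape, dtype=bool)
        off = self.offset_voxels
        sl = tuple(slice(o, o + s) for o, s in zip(off, mask.shape))
        out[sl] = mask.data
        return BinaryMask(out, mask.spacing, original_origin)


def auto_crop(volume: VolumeImage, air_threshold_hu: float = -500.0) -> CropResult:
    """Crop a thoracic volume to the lung region.

    Voxels below ``air_threshold_hu`` are air-like (airway lumen and lung
    parenchyma).  Air components touching a lateral image border are
    body-exterior air and are discarded; the bounding box of the remaining
    air, padded by 2 voxels and clipped to the image, is returned.  Raises
    :class:`DataError` if no interior air component exists.
    """
    air = volume.data < air_threshold_hu
    lab, n = ndimage.label(air)  # 6-connectivity
    if n == 0:
        raise DataError("no lung-like region: no voxel below the air threshold")
    border_labels = np.unique(np.concatenate([
        lab[:, 0, :].ravel(), lab[:, -1, :].ravel(),
        lab[:, :, 0].ravel(), lab[:, :, -1].ravel(),
    ]))
    border_labels = border_labels[border_labels != 0]
    interior = air & ~np.isin(lab, border_labels)
    if not interior.any():
        raise DataError("no lung-like region: all air touches the lateral border")
    idx = np.argwhere(interior)
    lo = np.maximum(idx.min(axis=0) - 2, 0)
    hi = np.minimum(idx.max(axis=0) + 3, volume.shape)  # exclusive
    sl = tuple(slice(l, h) for l, h in zip(lo, hi))
    new_origin = tuple(o + l * s for o, l, s in zip(volume.origin, lo, volume.spacing))
    cropped = VolumeImage(volume.data[sl].copy(), volume.spacing, new_origin)
    return CropResult(cropped, tuple(int(l) for l in lo))


def _eigvals_sym3(a11, a12, a13, a22, a23, a33):
    """Eigenvalues of symmetric 3×3 matrices, vectorised (trigonometric form).

    Returns three arrays, unordered.  Accurate to ~1e-6 relative, which is
    ample for a thresholded likelihood map.
    """
    q = (a11 + a22 + a33) / 3.0
    b11, b22, b33 = a11 - q, a22 - q, a33 - q
    p2 = b11 * b11 + b22 * b22 + b33 * b33 + 2.0 * (a12 * a12 + a13 * a13 + a23 * a23)
    p = np.sqrt(np.maximum(p2 / 6.0, 0.0))
    safe_p = np.where(p > 0, p, 1.0)
    # det(B)/p^3 with B = A - qI
    detb = (b11 * (b22 * b33 - a23 * a23)
            - a12 * (a12 * b33 - a23 * a13)
            + a13 * (a12 * a23 - b22 * a13))
    r = np.clip(detb / (2.0 * safe_p ** 3), -1.0, 1.0)
    phi = np.arccos(r) / 3.0
    e1 = q + 2.0 * p * np.cos(phi)
    e3 = q + 2.0 * p * np.cos(phi + 2.0 * np.pi / 3.0)
    e2 = 3.0 * q - e1 - e3
    zero = p == 0
    if np.any(zero):
        for e in (e1, e2, e3):
            e[zero] = q[zero] if np.ndim(q) else q
    return e1, e2, e3


def tube_probability(volume: VolumeImage,
                     radii_mm=DEFAULT_SCALES_MM,
                     contrast_hu: float = 100.0) -> TubeProbabilityMap:
    """Multi-scale dark-tube likelihood map.

    Parameters
    ----------
    radii_mm : scales of the filter bank, in mm; each must be at least the
        largest voxel spacing.  The Gaussian width per scale is r/sqrt(2),
        near-optimal for a cylinder of radius r.
    contrast_hu : intensity contrast (HU) at which the structureness term
        saturates; ~100 HU suits the lumen/parenchyma contrast of lung CT.
    """
    radii = tuple(float(r) for r in np.atleast_1d(radii_mm))
    if len(radii) == 0:
        raise ParameterError("radii_mm must be non-empty")
    if min(radii) < max(volume.spacing):
        raise ParameterError(
            f"scale {min(radii)} mm is below the voxel spacing {max(volume.spacing)} mm")
    if contrast_hu <= 0:
        raise ParameterError("contrast_hu must be positive")

    data = volume.data.astype(np.float64)
    # truncated Gaussian-derivative kernels do not annihilate constants
    # exactly; centring the data makes the filter exactly invariant to a
    # global HU offset and exactly zero on constant volumes
    data -= data.mean()
    spacing = np.asarray(volume.spacing, dtype=np.float64)
    alpha2 = 2.0 * 0.5 ** 2
    beta2 = 2.0 * 0.25 ** 2
    c2 = 2.0 * (contrast_hu / 2.0) ** 2
    response = np.zeros(volume.shape, dtype=np.float32)

    orders = [(2, 0, 0), (1, 1, 0), (1, 0, 1), (0, 2, 0), (0, 1, 1), (0, 0, 2)]
    for r in radii:
        sigma_mm = r / np.sqrt(2.0)
        sigma_vox = sigma_mm / spacing
        h = []
        for o in orders:
            d = ndimage.gaussian_filter(data, sigma=sigma_vox, order=o, mode="nearest")
            scale = sigma_mm ** 2 / np.prod(spacing ** np.asarray(o))
            h.append(d * scale)
        hzz, hzy, hzx, hyy, hyx, hxx = h
        # value-ordered eigenvalues lc >= lb >= la (the trigonometric form
        # returns them in descending order); the response depends only on
        # the two largest, which keeps it continuous in the Hessian entries
        lc, lb, la = _eigvals_sym3(hzz, hzy, hzx, hyy, hyx, hxx)
        tube = lb > 0  # dark cross-section: both in-plane curvatures positive
        lc_safe = np.where(lc > 0, lc, 1.0)
        ra2 = np.where(tube, (lb / lc_safe) ** 2, 0.0)
        # suppress saddles (bright ridge through a dark plane): a strongly
        # negative axial eigenvalue is not tube-like
        neg = np.minimum(la, 0.0)
        saddle = np.exp(-(neg / lc_safe) ** 2 / beta2)
        s2 = la * la + lb * lb + lc * lc
        v = saddle * (1.0 - np.exp(-ra2 / alpha2)) * (1.0 - np.exp(-s2 / c2))
        v = np.where(tube, v, 0.0).astype(np.float32)
        np.maximum(response, v, out=response)

    peak = float(response.max())
    if peak <= 1e-6:  # no real structure anywhere: numerical residue only
        response[:] = 0.0
    else:
        response /= peak
    return TubeProbabilityMap(response, radii, volume.spacing, volume.origin)
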