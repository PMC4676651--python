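"""Core grid containers and package exceptions.

All 3-D grids use (z, y, x) axis order, slices first, 0-based voxel
indices.  World coordinates are millimetres with
``world = origin + index * spacing`` per axis; no direction cosines
(axis-aligned acquisitions only).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class AirtreeError(Exception):
    """Base class for all package errors."""


class ParameterError(AirtreeError):
    """A parameter is outside its legal range (CLI exit code 2)."""


class DataError(AirtreeError):
    """Input data is missing, malformed or inconsistent (CLI exit code 3)."""


# Reference-label codes (EXACT09-style).
LABEL_BACKGROUND = 0
LABEL_CORRECT = 1
LABEL_WRONG = 2
LABEL_UNKNOWN = 3


def _as_triple(v) -> tuple[float, float, float]:
    a = tuple(float(x) for x in np.atleast_1d(v).ravel())
    if len(a) == 1:
        a = a * 3
    if len(a) != 3:
        raise ParameterError(f"expected 3 components, got {len(a)}")
    return a  # type: ignore[return-value]


@dataclass
class VolumeImage:
    """A 3-D scalar CT-like grid in Hounsfield units.

    Parameters
    ----------
    data : ndarray, shape (nz, ny, nx)
        Voxel intensities in HU (signed).
    spacing : (3,) float
        Per-axis voxel size in mm, (z, y, x) order.
    origin : (3,) float
        World position of voxel (0, 0, 0) in mm, (z, y, x) order.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ParameterError("volume data must be a non-empty 3-D array")
        self.spacing = _as_triple(self.spacing)
        self.origin = _as_triple(self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ParameterError(f"spacing must be strictly positive, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise DataError("volume contains non-finite HU values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        """Map (…, 3) voxel indices to (…, 3) world mm coordinates."""
        idx = np.asarray(idx, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def world_to_index(self, pts: np.ndarray) -> np.ndarray:
        """Map (…, 3) world mm coordinates to nearest (…, 3) voxel indices."""
        pts = np.asarray(pts, dtype=float)
        return np.rint((pts - np.asarray(self.origin)) / np.asarray(self.spacing)).astype(int)


@dataclass
class BinaryMask:
    """A boolean grid aligned to a :class:`VolumeImage` (same shape/spacing/origin)."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ParameterError("mask data must be 3-D")
        self.spacing = _as_triple(self.spacing)
        self.origin = _as_triple(self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ParameterError(f"spacing must be strictly positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def like(self, data: np.ndarray) -> "BinaryMask":
        """New mask on the same grid."""
        return BinaryMask(data, self.spacing, self.origin)

    index_to_world = VolumeImage.index_to_world
    world_to_index = VolumeImage.world_to_index


@dataclass
class ReferenceLabels:
    """EXACT09-style reference labelling of a volume.

    ``labels`` holds one of LABEL_BACKGROUND / LABEL_CORRECT / LABEL_WRONG /
    LABEL_UNKNOWN per voxel (mutually exclusive, exhaustive).  ``branch_id``
    assigns every *correct* voxel the integer id of the ground-truth branch
    it belongs to (−1 elsewhere).  The trachea (generation 1) and the two
    main bronchi (generation 2) carry dedicated sub-masks because the
    evaluation formulas exclude them from specific counts.
    """

    labels: np.ndarray
    branch_id: np.ndarray
    trachea_mask: BinaryMask
    main_bronchi_mask: BinaryMask
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    branch_generation: dict[int, int] = field(default_factory=dict)

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        self.branch_id = np.asarray(self.branch_id)
        if self.labels.shape != self.branch_id.shape:
            raise ParameterError("labels and branch_id shapes differ")
        self.spacing = _as_triple(self.spacing)
        self.origin = _as_triple(self.origin)
        correct = self.labels == LABEL_CORRECT
        if np.any(self.branch_id[correct] < 0):
            raise DataError("a correct voxel is missing its branch_id")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def correct_mask(self) -> np.ndarray:
        return self.labels == LABEL_CORRECT

    @property
    def wrong_mask(self) -> np.ndarray:
        return self.labels == LABEL_WRONG

    @property
    def unknown_mask(self) -> np.ndarray:
        return self.labels == LABEL_UNKNOWN

    index_to_world = VolumeImage.index_to_world
    world_to_index = VolumeImage.world_to_index
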