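"""Per-method airway-tree measurements.

Branch counts per generation, total centerline length (mm of world space),
segmented volume (voxel count × voxel volume) and the Pearson correlation
used to compare measurement series between methods.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import BinaryMask, ParameterError
from .tree import CenterlineTree, validate_tree


@dataclass
class GenerationHistogram:
    """Branch counts grouped by generation (trachea = generation 1)."""

    counts: dict[int, int]

    @property
    def total_branches(self) -> int:
        return sum(self.counts.values())

    @property
    def max_generation(self) -> int:
        return max(self.counts) if self.counts else 0


def branches_per_generation(tree: CenterlineTree) -> GenerationHistogram:
    """Histogram of branch counts per generation."""
    validate_tree(tree)
    counts: dict[int, int] = {}
    for b in tree.branches:
        counts[b.generation] = counts.get(b.generation, 0) + 1
    return GenerationHistogram(counts)


def total_length(tree: CenterlineTree) -> float:
    """Total centerline length in mm: sum of branch polyline lengths.

    Junction points are shared between parent and child polylines but each
    inter-point segment belongs to exactly one branch, so nothing is
    counted twice.  Only branches connected to the root are present in a
    valid tree, so disconnected fragments never contribute.
    """
    validate_tree(tree)
    return float(sum(b.length_mm for b in tree.branches))


def mask_volume(mask: BinaryMask) -> float:
    """Segmented volume in mm³: true-voxel count × single-voxel volume."""
    return float(np.count_nonzero(mask.data)) * mask.voxel_volume_mm3


def pearson(x, y) -> float:
    """Pearson product-moment correlation between two measurement series."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or x.shape != y.shape or len(x) < 2:
        raise ParameterError("need two equal-length 1-D series of length >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ParameterError("zero variance in a series: correlation undefined")
    return float(stats.pearsonr(x, y).statistic)
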