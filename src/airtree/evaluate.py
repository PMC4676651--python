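"""EXACT09-style evaluation of a candidate airway segmentation.

A reference labelling marks every voxel correct / wrong / unknown (plus
background) and assigns each correct voxel to a ground-truth branch.  The
measures are

* branch detection: Nseg / Nref × 100 %, a reference branch counting as
  detected when at least one candidate-centerline point falls inside a
  voxel carrying its branch id;
* tree-length detection: Lseg / Lref × 100 %, measured along the
  *reference* centerline — a segment counts when both endpoints lie in
  segmented voxels — so Lseg ≤ Lref by construction;
* false-positive rate: Nw / (Nc + Nw) × 100 %, where Nc and Nw count
  segmented voxels overlapping correct resp. wrong regions; voxels
  overlapping unknown regions count in neither;
* leakage: 26-connected components of wrong-labelled segmented voxels
  (count) and their total volume in mm³.

Exclusions: the trachea is excluded from every measure; the two main
bronchi are additionally excluded from the voxel counts Nc / Nw feeding
the false-positive rate.  Main bronchi still count in branch and length
detection and, since they are correct-labelled, never appear as leakage.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
from scipy import ndimage

from .core import BinaryMask, DataError, ReferenceLabels
from .tree import CenterlineTree

_B26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class EvaluationResult:
    """One row of an evaluation table for a single case and method."""

    branch_count: int            # Nseg
    branch_total: int            # Nref
    branch_detected_pct: float
    tree_length_detected_cm: float   # Lseg
    tree_length_total_cm: float      # Lref
    tree_length_pct: float
    leakage_count: int
    leakage_volume_mm3: float
    false_positive_rate_pct: float
    n_correct_voxels: int        # Nc
    n_wrong_voxels: int          # Nw

    def to_json(self, path: str | None = None) -> str:
        s = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s + "\n")
        return s


def _check_grids(seg: BinaryMask, ref: ReferenceLabels) -> None:
    if seg.shape != ref.shape:
        raise DataError(f"grid mismatch: segmentation {seg.shape} vs reference {ref.shape}")


def overlap_counts(seg: BinaryMask, ref: ReferenceLabels) -> tuple[int, int]:
    """Voxel counts (Nc, Nw) of the segmentation over correct / wrong regions.

    Unknown-region voxels count in neither; trachea and main-bronchus
    voxels are excluded (these counts feed the false-positive rate, for
    which both exclusions apply).
    """
    _check_grids(seg, ref)
    excl = ref.trachea_mask.data | ref.main_bronchi_mask.data
    s = seg.data & ~excl
    nc = int(np.count_nonzero(s & ref.correct_mask))
    nw = int(np.count_nonzero(s & ref.wrong_mask))
    return nc, nw


def false_positive_rate(nc: int, nw: int) -> float:
    """Nw / (Nc + Nw) × 100 %."""
    if nc + nw == 0:
        raise DataError("empty segmentation after exclusions")
    return 100.0 * nw / (nc + nw)


def _branch_ids_by_generation(ref: ReferenceLabels, generation: int) -> set[int]:
    return {bid for bid, g in ref.branch_generation.items() if g == generation}


def branch_detection(seg_tree: CenterlineTree, ref: ReferenceLabels,
                     ref_tree: CenterlineTree) -> tuple[int, int, float]:
    """(Nseg, Nref, percentage) of reference branches detected.

    The trachea (generation-1 branch) is excluded from both counts.
    """
    trachea_ids = _branch_ids_by_generation(ref, 1)
    all_ids = set(ref.branch_generation) - trachea_ids
    nref = len(all_ids)
    detected: set[int] = set()
    if seg_tree is not None and seg_tree.branches:
        idx = ref.world_to_index(seg_tree.all_points())
        ok = np.all((idx >= 0) & (idx < np.asarray(ref.shape)), axis=1)
        idx = idx[ok]
        hit = ref.branch_id[idx[:, 0], idx[:, 1], idx[:, 2]]
        detected = set(int(h) for h in np.unique(hit) if h >= 0) & all_ids
    nseg = len(detected)
    pct = 100.0 * nseg / nref if nref else 0.0
    return nseg, nref, pct


def tree_length_detected(seg: BinaryMask, ref_tree: CenterlineTree,
                         ref: ReferenceLabels) -> tuple[float, float, float]:
    """(Lseg, Lref, percentage) of reference tree length covered, in cm.

    Lref sums reference branch lengths excluding the trachea; a reference
    centerline segment contributes to Lseg when both its endpoints lie in
    segmented voxels.
    """
    _check_grids(seg, ref)
    lref_mm = 0.0
    lseg_mm = 0.0
    shape = np.asarray(ref.shape)
    for b in ref_tree.branches:
        if b.generation == 1:
            continue
        lref_mm += b.length_mm
        if len(b.points) < 2:
            continue
        idx = ref.world_to_index(b.points)
        ok = np.all((idx >= 0) & (idx < shape), axis=1)
        covered = np.zeros(len(idx), dtype=bool)
        sub = idx[ok]
        covered[ok] = seg.data[sub[:, 0], sub[:, 1], sub[:, 2]]
        seglen = np.linalg.norm(np.diff(b.points, axis=0), axis=1)
        lseg_mm += float(seglen[covered[:-1] & covered[1:]].sum())
    if lref_mm == 0:
        raise DataError("reference tree has zero non-trachea length")
    return lseg_mm / 10.0, lref_mm / 10.0, 100.0 * lseg_mm / lref_mm


def leakage_stats(seg: BinaryMask, ref: ReferenceLabels) -> tuple[int, float]:
    """(count, volume mm³) of leakage: wrong-labelled segmented voxels,
    grouped into 26-connected components.  Unknown voxels are not leakage."""
    _check_grids(seg, ref)
    leak = seg.data & ref.wrong_mask
    _, count = ndimage.label(leak, structure=_B26)
    volume = float(np.count_nonzero(leak)) * ref.voxel_volume_mm3
    return int(count), volume


def evaluate_segmentation(seg: BinaryMask, seg_tree: CenterlineTree,
                          ref: ReferenceLabels,
                          ref_tree: CenterlineTree) -> EvaluationResult:
    """Full evaluation record for one candidate segmentation."""
    nc, nw = overlap_counts(seg, ref)
    fpr = false_positive_rate(nc, nw)
    nseg, nref, bpct = branch_detection(seg_tree, ref, ref_tree)
    lseg, lref, lpct = tree_length_detected(seg, ref_tree, ref)
    count, volume = leakage_stats(seg, ref)
    return EvaluationResult(
        branch_count=nseg,
        branch_total=nref,
        branch_detected_pct=bpct,
        tree_length_detected_cm=lseg,
        tree_length_total_cm=lref,
        tree_length_pct=lpct,
        leakage_count=count,
        leakage_volume_mm3=volume,
        false_positive_rate_pct=fpr,
        n_correct_voxels=nc,
        n_wrong_voxels=nw,
    )
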