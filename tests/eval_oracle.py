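"""Brute-force re-implementation of the evaluation formulas, plus a tiny
randomized reference generator.

Everything here is written independently of the package's vectorized
implementation: plain Python loops over voxels and points, intended for
grids up to ~32³.  The random generator produces small synthetic reference
labellings with a valid Y-shaped (or deeper) reference tree on a
unit-spacing grid so the formulas can be cross-checked exhaustively.
"""

import math

import numpy as np

from airtree import BinaryMask, Branch, CenterlineTree, ReferenceLabels
from airtree.core import LABEL_BACKGROUND, LABEL_CORRECT, LABEL_UNKNOWN, LABEL_WRONG


def o_overlap_counts(seg, ref):
    nc = nw = 0
    excl = ref.trachea_mask.data | ref.main_bronchi_mask.data
    nz, ny, nx = ref.shape
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                if not seg.data[z, y, x] or excl[z, y, x]:
                    continue
                if ref.labels[z, y, x] == LABEL_CORRECT:
                    nc += 1
                elif ref.labels[z, y, x] == LABEL_WRONG:
                    nw += 1
    return nc, nw


def o_false_positive_rate(nc, nw):
    return 100.0 * nw / (nc + nw)


def o_branch_detection(seg_tree, ref, ref_tree):
    trachea = {b for b, g in ref.branch_generation.items() if g == 1}
    eligible = set(ref.branch_generation) - trachea
    hit = set()
    for b in seg_tree.branches:
        for p in b.points:
            i = tuple(int(round((p[k] - ref.origin[k]) / ref.spacing[k]))
                      for k in range(3))
            if all(0 <= i[k] < ref.shape[k] for k in range(3)):
                bid = int(ref.branch_id[i])
                if bid in eligible:
                    hit.add(bid)
    nref = len(eligible)
    return len(hit), nref, 100.0 * len(hit) / nref if nref else 0.0


def o_tree_length_detected(seg, ref_tree, ref):
    lref = lseg = 0.0
    for b in ref_tree.branches:
        if b.generation == 1:
            continue
        pts = b.points
        inside = []
        for p in pts:
            i = tuple(int(round((p[k] - ref.origin[k]) / ref.spacing[k]))
                      for k in range(3))
            ok = all(0 <= i[k] < ref.shape[k] for k in range(3))
            inside.append(ok and bool(seg.data[i]))
        for a in range(len(pts) - 1):
            d = math.dist(pts[a], pts[a + 1])
            lref += d
            if inside[a] and inside[a + 1]:
                lseg += d
    return lseg / 10.0, lref / 10.0, 100.0 * lseg / lref


def o_leakage_stats(seg, ref):
    wrong = [tuple(v) for v in np.argwhere(seg.data & (ref.labels == LABEL_WRONG))]
    wrong_set = set(wrong)
    seen = set()
    count = 0
    for v in wrong:
        if v in seen:
            continue
        count += 1
        stack = [v]
        seen.add(v)
        while stack:
            c = stack.pop()
            for dz in (-1, 0, 1):
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        w = (c[0] + dz, c[1] + dy, c[2] + dx)
                        if w in wrong_set and w not in seen:
                            seen.add(w)
                            stack.append(w)
    vol = len(wrong) * float(np.prod(ref.spacing))
    return count, vol


def random_reference_case(rng, size=16):
    """A small random labelled grid, its reference tree, and a random
    candidate segmentation + tree."""
    shape = (size, size, size)
    labels = np.full(shape, LABEL_BACKGROUND, np.uint8)
    branch_id = np.full(shape, -1, np.int32)

    def carve(start, step, n, bid):
        pts = []
        p = np.asarray(start)
        for _ in range(n):
            if not all(0 <= p[k] < size for k in range(3)):
                break
            labels[tuple(p)] = LABEL_CORRECT
            if branch_id[tuple(p)] < 0:
                branch_id[tuple(p)] = bid
            pts.append(p.astype(float).copy())
            p = p + step
        return np.asarray(pts)

    y0, x0 = rng.integers(3, size - 9, 2)
    n0 = int(rng.integers(4, 7))
    p0 = carve((1, y0, x0), (1, 0, 0), n0, 0)
    end = p0[-1].astype(int)
    n1 = int(rng.integers(3, min(size - 2 - end[1], 7)))
    n2 = int(rng.integers(3, min(size - 2 - end[2], 7)))
    p1 = carve(end, (0, 1, 0), n1 + 1, 1)
    p2 = carve(end, (0, 0, 1), n2 + 1, 2)

    tree = CenterlineTree([
        Branch(p0, 1, None), Branch(p1, 2, 0), Branch(p2, 2, 0)])

    correct = labels == LABEL_CORRECT
    from scipy import ndimage
    rind = ndimage.binary_dilation(correct, np.ones((3, 3, 3), bool)) & ~correct
    labels[rind] = LABEL_UNKNOWN
    rest = labels == LABEL_BACKGROUND
    wrongify = rest & (rng.random(shape) < 0.7)
    labels[wrongify] = LABEL_WRONG

    trachea = BinaryMask(branch_id == 0, (1, 1, 1))
    bronchi = BinaryMask(branch_id == 1, (1, 1, 1))
    ref = ReferenceLabels(labels, np.where(correct, branch_id, -1),
                          trachea, bronchi, (1, 1, 1), (0, 0, 0),
                          {0: 1, 1: 2, 2: 2})

    seg_data = (correct & (rng.random(shape) < 0.8)) \
        | ((labels == LABEL_WRONG) & (rng.random(shape) < 0.05)) \
        | (rind & (rng.random(shape) < 0.3))
    seg_data[tuple(p0[0].astype(int))] = True  # never empty after exclusions
    seg_data[tuple(p1[-1].astype(int))] = True
    seg = BinaryMask(seg_data, (1, 1, 1))

    # candidate tree: reference branches, randomly truncated
    cand = []
    for i, b in enumerate(tree.branches):
        k = int(rng.integers(2, len(b.points) + 1))
        cand.append(Branch(b.points[:k] if i == 0 else b.points[:k],
                           b.generation, b.parent))
    # keep junction consistency: children must start at parent's last point
    cand[0] = Branch(tree.branches[0].points, 1, None)
    seg_tree = CenterlineTree(cand)
    return seg, seg_tree, ref, tree
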