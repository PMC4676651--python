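"""Centerline extraction: from a tube-probability map or by mask thinning.

Both routes end in the same machinery: a 26-connected binary object is
reduced to a one-voxel-wide, topology-preserving skeleton (Lee's 3-D
thinning, via scikit-image), skeleton voxels are linked into a graph whose
edges join 26-neighbours weighted by their Euclidean mm distance, a
minimum spanning tree removes any residual skeleton loops, the tree is
rooted at the maximal-z endpoint (the cranial end of the trachea), short
terminal spurs are pruned, and the result is decomposed into branches with
generation indices (trachea = 1).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import minimum_spanning_tree
from skimage.morphology import skeletonize

from .core import BinaryMask, DataError, ParameterError, VolumeImage
from .tree import Branch, CenterlineTree, tree_from_point_graph, validate_tree
from .tdf import TubeProbabilityMap

_B26 = np.ones((3, 3, 3), dtype=bool)

# forward half of the 26-neighbourhood (avoids double edges)
_FWD_OFFSETS = [(dz, dy, dx)
                for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
                if (dz, dy, dx) > (0, 0, 0)]


def _extend_tips(tree: CenterlineTree, comp: np.ndarray, spacing, origin) -> CenterlineTree:
    """Extend the root start and every terminal end along the local branch
    direction while the object's interior depth supports it.

    Thinning erodes the ends of a tube by up to one radius.  Marching from
    each tip along the branch direction, a point is appended while it stays
    inside the component and the Euclidean distance-to-boundary does not
    fall off faster than half the distance travelled — inside a tube the
    depth is constant, at a rounded end it drops at unit rate, so the march
    stops right where the tube actually ends.
    """
    spacing = np.asarray(spacing, dtype=float)
    origin = np.asarray(origin, dtype=float)
    edt = ndimage.distance_transform_edt(comp, sampling=spacing)
    shape = np.asarray(comp.shape)
    step = 0.5 * float(spacing.min())
    slack = 0.7 * float(spacing.max())

    def depth(p):
        i = np.rint((p - origin) / spacing).astype(int)
        if np.any(i < 0) or np.any(i >= shape) or not comp[tuple(i)]:
            return None
        return float(edt[tuple(i)])

    def march(pts, at_end: bool):
        k = min(len(pts), 6)
        seg = pts[-k:] if at_end else pts[:k][::-1]
        d = seg[-1] - seg[0]
        n = np.linalg.norm(d)
        if len(seg) < 2 or n < 1e-9:
            return pts
        d = d / n
        tip = seg[-1]
        d0 = depth(tip)
        if d0 is None:
            return pts
        anchor_depth, anchor_dist = d0, 0.0
        new = []
        for j in range(1, 201):
            dist = j * step
            p = tip + d * dist
            dp = depth(p)
            if dp is None or dp < anchor_depth - 0.5 * (dist - anchor_dist) - slack:
                break
            if dp >= anchor_depth:
                anchor_depth, anchor_dist = dp, dist
            new.append(p)
        if not new:
            return pts
        ext = np.asarray(new)
        return np.vstack([pts, ext]) if at_end else np.vstack([ext[::-1], pts])

    children = {i: tree.children_of(i) for i in range(len(tree.branches))}
    out = []
    for i, b in enumerate(tree.branches):
        pts = b.points
        if i == 0 and len(pts) >= 2:
            pts = march(pts, at_end=False)
        if not children[i] and len(pts) >= 2:
            pts = march(pts, at_end=True)
        out.append(Branch(pts, b.generation, b.parent))
    return CenterlineTree(out)


def _skeleton_to_tree(skel: np.ndarray, spacing, origin,
                      min_spur_length_mm: float,
                      comp: np.ndarray | None = None) -> CenterlineTree:
    coords = np.argwhere(skel)
    if len(coords) == 0:
        raise DataError("empty skeleton")
    pts = np.asarray(origin) + coords * np.asarray(spacing)
    if len(coords) == 1:
        return CenterlineTree([Branch(pts, 1, None)])

    index = {tuple(c): i for i, c in enumerate(coords)}
    rows, cols, w = [], [], []
    for i, c in enumerate(coords):
        for off in _FWD_OFFSETS:
            nb = (c[0] + off[0], c[1] + off[1], c[2] + off[2])
            j = index.get(nb)
            if j is not None:
                rows.append(i)
                cols.append(j)
                w.append(float(np.linalg.norm(np.asarray(off) * np.asarray(spacing))))
    if not rows:
        raise DataError("skeleton voxels are not 26-connected")
    g = coo_matrix((w, (rows, cols)), shape=(len(coords), len(coords)))
    mst = minimum_spanning_tree(g).tocoo()
    edges = list(zip(mst.row.tolist(), mst.col.tolist()))

    deg = np.zeros(len(coords), dtype=int)
    for a, b in edges:
        deg[a] += 1
        deg[b] += 1
    endpoints = np.flatnonzero(deg == 1)
    if len(endpoints) == 0:
        raise DataError("skeleton graph has no endpoint")
    # root: endpoint with maximal world z; ties resolved by raster order
    root = int(endpoints[np.argmax(pts[endpoints, 0])])
    tree = tree_from_point_graph(pts, edges, root)
    tree = prune_spurs(tree, min_spur_length_mm)
    if comp is not None:
        tree = _extend_tips(tree, comp, spacing, origin)
    validate_tree(tree)
    return tree


def _solidify(comp: np.ndarray) -> np.ndarray:
    """Fill cavities in a thresholded tube component.

    Scale-space interference leaves one-voxel gaps, and the response dips
    at the centre of blunt tube ends, leaving ring-shaped cross-sections
    there; a skeleton of such a shell is a loop, not a curve.  Closing
    bridges the small gaps, and hole filling (3-D, then per-slice 2-D
    along each axis to catch end-pockets open on one side) restores a
    solid tube.
    """
    comp = ndimage.binary_closing(comp, structure=_B26, iterations=1)
    comp = ndimage.binary_fill_holes(comp)
    for axis in range(3):
        comp = np.moveaxis(comp, axis, 0)
        for k in range(comp.shape[0]):
            comp[k] = ndimage.binary_fill_holes(comp[k])
        comp = np.moveaxis(comp, 0, axis)
    return comp


def _largest_cc(mask: np.ndarray) -> np.ndarray:
    lab, n = ndimage.label(mask, structure=_B26)
    if n == 0:
        raise DataError("mask has no foreground voxel")
    if n == 1:
        return mask.astype(bool)
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    return lab == (1 + int(np.argmax(sizes)))


def extract_centerline(tpm: TubeProbabilityMap, volume: VolumeImage,
                       probability_threshold: float = 0.15,
                       min_spur_length_mm: float | None = None) -> CenterlineTree:
    """Centerline tree from a tube-probability map.

    Voxels with probability >= threshold are selected; the 26-connected
    component containing the strongest response (probability 1 after
    rescaling — inside the trachea, the dominant tube) is closed,
    skeletonized and decomposed into branches.

    ``min_spur_length_mm`` defaults to 2 × mean voxel spacing.
    """
    if not 0 < probability_threshold < 1:
        raise ParameterError("probability_threshold must lie in (0, 1)")
    sel = tpm.data >= probability_threshold
    if not sel.any():
        raise DataError("no airway candidate: no voxel above the probability threshold")
    if min_spur_length_mm is None:
        min_spur_length_mm = 2.0 * float(np.mean(volume.spacing))
    lab, _ = ndimage.label(sel, structure=_B26)
    peak = np.unravel_index(int(np.argmax(tpm.data)), tpm.data.shape)
    comp = lab == lab[peak]
    comp = _solidify(comp)
    skel = skeletonize(comp)
    return _skeleton_to_tree(skel, volume.spacing, volume.origin,
                             min_spur_length_mm, comp)


def thinning_centerline(mask: BinaryMask,
                        min_spur_length_mm: float | None = None) -> CenterlineTree:
    """Centerline tree by topology-preserving thinning of a binary mask.

    This is the route used for masks exported from threshold-based
    segmentations, which carry no probability map.
    """
    if not mask.data.any():
        raise DataError("empty mask")
    if min_spur_length_mm is None:
        min_spur_length_mm = 2.0 * float(np.mean(mask.spacing))
    comp = _largest_cc(mask.data)
    skel = skeletonize(comp)
    return _skeleton_to_tree(skel, mask.spacing, mask.origin,
                             min_spur_length_mm, comp)


def prune_spurs(tree: CenterlineTree, min_length_mm: float) -> CenterlineTree:
    """Remove terminal branches shorter than ``min_length_mm``.

    After each removal round, junctions left with a single child are
    dissolved (parent and child polylines merged) and generations are
    recomputed.  Idempotent at fixed ``min_length_mm``; the root branch is
    never removed.
    """
    if min_length_mm < 0:
        raise ParameterError("min_length_mm must be >= 0")
    branches = [Branch(b.points.copy(), b.generation, b.parent) for b in tree.branches]

    def children_map(brs):
        ch: dict[int, list[int]] = {i: [] for i in range(len(brs))}
        for i, b in enumerate(brs):
            if b.parent is not None:
                ch[b.parent].append(i)
        return ch

    while True:
        ch = children_map(branches)
        remove = sorted(i for i, b in enumerate(branches)
                        if b.parent is not None and not ch[i]
                        and b.length_mm < min_length_mm)
        merged = False
        if remove:
            keep = [i for i in range(len(branches)) if i not in set(remove)]
            remap = {old: new for new, old in enumerate(keep)}
            branches = [Branch(branches[i].points, branches[i].generation,
                               None if branches[i].parent is None
                               else remap[branches[i].parent]) for i in keep]
            merged = True
        else:
            # dissolve pass-through junctions
            for i in range(len(branches)):
                c = ch[i]
                if len(c) == 1:
                    j = c[0]
                    merged_pts = np.vstack([branches[i].points, branches[j].points[1:]])
                    branches[i] = Branch(merged_pts, branches[i].generation,
                                         branches[i].parent)
                    keep = [k for k in range(len(branches)) if k != j]
                    remap = {old: new for new, old in enumerate(keep)}
                    new_branches = []
                    for k in keep:
                        b = branches[k]
                        parent = b.parent
                        if parent == j:
                            parent = i
                        new_branches.append(Branch(
                            b.points, b.generation,
                            None if parent is None else remap[parent]))
                    branches = new_branches
                    merged = True
                    break
        if not merged:
            break

    # recompute generations (root = 1, +1 per junction)
    ch = children_map(branches)
    gen = {0: 1}
    stack = [0]
    while stack:
        i = stack.pop()
        for j in ch[i]:
            gen[j] = gen[i] + 1
            stack.append(j)
    out = [Branch(b.points, gen[i], b.parent) for i, b in enumerate(branches)]
    result = CenterlineTree(out)
    validate_tree(result)
    return result
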