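"""Synthetic branching-airway CT phantoms with exact ground truth.

The phantom emulates the features of a thoracic CT that the segmentation
pipeline relies on: a dark air-filled lumen (≈ −1000 HU) enclosed by a
brighter airway wall (soft tissue, ≈ 0 HU), embedded in lung parenchyma
(≈ −850 HU), with optional additive Gaussian noise.  Geometry is a
dichotomously branching tree: a vertical trachea (generation 1) splits at
the carina into two main bronchi (generation 2); every child is rotated by
± the branching angle in planes that alternate between generations, and
radius and length taper geometrically.  Each branch is rendered as a
capsule (cylinder with hemispherical caps), so the lumen is sealed by wall
tissue at the cranial end of the trachea and at every terminal branch.

Alongside the HU volume the generator returns the exact lumen mask, the
ground-truth centerline tree (points sampled along each branch axis), and
EXACT09-style reference labels: correct = lumen, unknown = a one-voxel rind
around the lumen, wrong = everything else, plus trachea and main-bronchus
sub-masks and a per-voxel branch id.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import (
    AirtreeError,
    BinaryMask,
    LABEL_CORRECT,
    LABEL_UNKNOWN,
    LABEL_WRONG,
    ParameterError,
    ReferenceLabels,
    VolumeImage,
)
from .tree import Branch, CenterlineTree, validate_tree

_B26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class PhantomSpec:
    """Parameters of a synthetic airway phantom.

    Radii and lengths taper geometrically per generation:
    ``radius(g) = root_radius_mm * radius_taper**(g-1)`` and likewise for
    branch length.  Defaults give trachea-like calibre (9 mm radius) down
    to small-bronchus calibre (2.2 mm at generation 5), consistent with
    adult airway anatomy, on 0.5 mm isotropic voxels.
    """

    generations: int = 4
    root_radius_mm: float = 9.0
    radius_taper: float = 0.7
    root_length_mm: float = 30.0
    length_taper: float = 0.7
    branching_angle_deg: float = 35.0
    spacing_mm: tuple[float, float, float] = (0.5, 0.5, 0.5)
    hu_lumen: float = -1000.0
    hu_wall: float = 0.0
    hu_parenchyma: float = -850.0
    wall_thickness_mm: float = 1.5
    noise_sigma_hu: float = 0.0
    seed: int = 0

    def __post_init__(self):
        self.spacing_mm = tuple(float(s) for s in np.atleast_1d(self.spacing_mm).ravel()) \
            if np.size(self.spacing_mm) == 3 else (float(self.spacing_mm),) * 3
        if self.generations < 1:
            raise ParameterError("generations must be >= 1")
        if not 0 < self.radius_taper < 1 or not 0 < self.length_taper < 1:
            raise ParameterError("tapers must lie in (0, 1)")
        if not self.hu_lumen < self.hu_parenchyma < self.hu_wall:
            raise ParameterError("need hu_lumen < hu_parenchyma < hu_wall")
        if self.noise_sigma_hu < 0:
            raise ParameterError("noise_sigma_hu must be >= 0")
        r_deep = self.radius(self.generations)
        if r_deep < 2 * max(self.spacing_mm):
            raise ParameterError(
                f"generation {self.generations} radius {r_deep:.2f} mm is below "
                f"2 x max spacing {2 * max(self.spacing_mm):.2f} mm (tube unresolvable)")

    def radius(self, generation: int) -> float:
        return self.root_radius_mm * self.radius_taper ** (generation - 1)

    def length(self, generation: int) -> float:
        return self.root_length_mm * self.length_taper ** (generation - 1)


@dataclass
class PhantomBundle:
    """A generated phantom: HU volume, ground-truth lumen mask, centerline
    tree and reference labels, all on the same grid."""

    volume: VolumeImage
    lumen_mask: BinaryMask
    tree: CenterlineTree
    labels: ReferenceLabels
    spec: PhantomSpec = field(repr=False, default=None)


def _branch_axes(spec: PhantomSpec) -> list[dict]:
    """Analytic axis segments of the binary tree, in world mm (z, y, x).

    The trachea points in −z (cranial to caudal).  Children of a
    generation-g branch are rotated ±branching_angle about the parent
    direction, in the (z, y) plane for even g and the (z, x) plane for odd
    g, so consecutive bifurcations are roughly orthogonal as in real lungs.
    """
    theta = np.deg2rad(spec.branching_angle_deg)
    axes = [{"start": np.zeros(3), "dir": np.array([-1.0, 0.0, 0.0]),
             "generation": 1, "parent": None,
             "length": spec.length(1), "radius": spec.radius(1)}]
    frontier = [0]
    for g in range(2, spec.generations + 1):
        lateral = np.array([0.0, 1.0, 0.0]) if g % 2 == 0 else np.array([0.0, 0.0, 1.0])
        nxt = []
        for pi in frontier:
            p = axes[pi]
            d = p["dir"]
            u = lateral - np.dot(lateral, d) * d
            if np.linalg.norm(u) < 1e-9:  # parent runs along the lateral axis
                alt = np.array([0.0, 0.0, 1.0]) if g % 2 == 0 else np.array([0.0, 1.0, 0.0])
                u = alt - np.dot(alt, d) * d
            u /= np.linalg.norm(u)
            start = p["start"] + d * p["length"]
            for sign in (+1.0, -1.0):
                cd = np.cos(theta) * d + sign * np.sin(theta) * u
                cd /= np.linalg.norm(cd)
                axes.append({"start": start, "dir": cd, "generation": g,
                             "parent": pi, "length": spec.length(g),
                             "radius": spec.radius(g)})
                nxt.append(len(axes) - 1)
        frontier = nxt
    return axes


def _segment_distance(coords_z, coords_y, coords_x, a, b):
    """Distance of a voxel-coordinate grid block to segment a-b (mm)."""
    ab = b - a
    denom = float(np.dot(ab, ab))
    dz = coords_z - a[0]
    dy = coords_y - a[1]
    dx = coords_x - a[2]
    if denom < 1e-12:
        return np.sqrt(dz * dz + dy * dy + dx * dx)
    t = (dz * ab[0] + dy * ab[1] + dx * ab[2]) / denom
    np.clip(t, 0.0, 1.0, out=t)
    qz = dz - t * ab[0]
    qy = dy - t * ab[1]
    qx = dx - t * ab[2]
    return np.sqrt(qz * qz + qy * qy + qx * qx)


def generate_phantom(spec: PhantomSpec) -> PhantomBundle:
    """Render a :class:`PhantomSpec` into a :class:`PhantomBundle`.

    Deterministic for a fixed ``spec.seed``.  Raises
    :class:`ParameterError` if the phantom would not fit in 256³ voxels at
    the requested spacing.
    """
    axes = _branch_axes(spec)
    spacing = np.asarray(spec.spacing_mm)
    margin = spec.wall_thickness_mm + 2.0  # mm of parenchyma beyond every wall
    ends = []
    for ax in axes:
        ends.append(ax["start"] - (ax["radius"] + margin))
        ends.append(ax["start"] + ax["dir"] * ax["length"] + (ax["radius"] + margin))
        ends.append(ax["start"] + (ax["radius"] + margin))
        ends.append(ax["start"] + ax["dir"] * ax["length"] - (ax["radius"] + margin))
    lo = np.min(ends, axis=0)
    hi = np.max(ends, axis=0)
    shape = np.ceil((hi - lo) / spacing).astype(int) + 1
    if np.any(shape > 256):
        raise ParameterError(f"phantom would need {tuple(shape)} voxels (> 256 per axis)")
    origin = lo

    lumen = np.zeros(tuple(shape), dtype=bool)
    wall = np.zeros(tuple(shape), dtype=bool)
    branch_id = np.full(tuple(shape), -1, dtype=np.int32)
    best_signed = np.full(tuple(shape), np.inf, dtype=np.float32)

    for bi, ax in enumerate(axes):
        a = ax["start"]
        b = ax["start"] + ax["dir"] * ax["length"]
        pad = ax["radius"] + spec.wall_thickness_mm + max(spec.spacing_mm)
        blo = np.floor((np.minimum(a, b) - pad - origin) / spacing).astype(int)
        bhi = np.ceil((np.maximum(a, b) + pad - origin) / spacing).astype(int) + 1
        blo = np.maximum(blo, 0)
        bhi = np.minimum(bhi, shape)
        sl = tuple(slice(l, h) for l, h in zip(blo, bhi))
        zz = (np.arange(blo[0], bhi[0]) * spacing[0] + origin[0])[:, None, None]
        yy = (np.arange(blo[1], bhi[1]) * spacing[1] + origin[1])[None, :, None]
        xx = (np.arange(blo[2], bhi[2]) * spacing[2] + origin[2])[None, None, :]
        dist = _segment_distance(zz, yy, xx, a, b)
        lumen[sl] |= dist <= ax["radius"]
        wall[sl] |= dist <= ax["radius"] + spec.wall_thickness_mm
        signed = (dist - ax["radius"]).astype(np.float32)
        take = signed < best_signed[sl]
        best_signed[sl][take] = signed[take]
        bid = branch_id[sl]
        bid[take] = bi
        branch_id[sl] = bid

    hu = np.full(tuple(shape), spec.hu_parenchyma, dtype=np.float32)
    hu[wall & ~lumen] = spec.hu_wall
    hu[lumen] = spec.hu_lumen
    if spec.noise_sigma_hu > 0:
        rng = np.random.default_rng(spec.seed)
        hu += rng.normal(0.0, spec.noise_sigma_hu, size=hu.shape).astype(np.float32)

    volume = VolumeImage(hu, tuple(spacing), tuple(origin))
    lumen_mask = BinaryMask(lumen, tuple(spacing), tuple(origin))

    # ground-truth centerline: points along each axis at <= spacing/2 steps
    step = min(spec.spacing_mm) / 2.0
    branches = []
    for ax in axes:
        npts = max(int(np.ceil(ax["length"] / step)), 1) + 1
        t = np.linspace(0.0, ax["length"], npts)
        pts = ax["start"][None, :] + t[:, None] * ax["dir"][None, :]
        branches.append(Branch(pts, ax["generation"], ax["parent"]))
    tree = CenterlineTree(branches)
    validate_tree(tree)

    labels = np.full(tuple(shape), LABEL_WRONG, dtype=np.uint8)
    unknown = ndimage.binary_dilation(lumen, structure=_B26) & ~lumen
    labels[unknown] = LABEL_UNKNOWN
    labels[lumen] = LABEL_CORRECT
    branch_id_grid = np.where(lumen, branch_id, -1)
    gen_of = {bi: ax["generation"] for bi, ax in enumerate(axes)}
    g1 = np.isin(branch_id_grid, [bi for bi, g in gen_of.items() if g == 1])
    g2 = np.isin(branch_id_grid, [bi for bi, g in gen_of.items() if g == 2])
    ref = ReferenceLabels(
        labels=labels,
        branch_id=branch_id_grid,
        trachea_mask=BinaryMask(g1 & lumen, tuple(spacing), tuple(origin)),
        main_bronchi_mask=BinaryMask(g2 & lumen, tuple(spacing), tuple(origin)),
        spacing=tuple(spacing),
        origin=tuple(origin),
        branch_generation=gen_of,
    )
    return PhantomBundle(volume, lumen_mask, tree, ref, spec)


def punch_wall_hole(bundle: PhantomBundle, generation: int = 2,
                    hole_radius_mm: float = 1.5) -> VolumeImage:
    """Return a copy of the phantom volume with a hole punched through the
    airway wall of one branch of the given generation.

    Wall voxels within ``hole_radius_mm`` of a point on the branch surface
    are reset to the lumen HU, creating a direct air path from lumen to
    parenchyma — the defect through which threshold-based region growing
    leaks.
    """
    spec = bundle.spec
    axes = _branch_axes(spec)
    cands = [i for i, ax in enumerate(axes) if ax["generation"] == generation]
    if not cands:
        raise ParameterError(f"phantom has no generation-{generation} branch")
    ax = axes[cands[0]]
    mid = ax["start"] + ax["dir"] * (0.5 * ax["length"])
    # surface point: offset from the axis midpoint, perpendicular to the axis
    perp = np.array([0.0, 1.0, 0.0]) - ax["dir"][1] * ax["dir"]
    if np.linalg.norm(perp) < 1e-9:
        perp = np.array([0.0, 0.0, 1.0]) - ax["dir"][2] * ax["dir"]
    perp /= np.linalg.norm(perp)
    center = mid + perp * (ax["radius"] + spec.wall_thickness_mm / 2.0)
    vol = bundle.volume
    shape = np.asarray(vol.shape)
    spacing = np.asarray(vol.spacing)
    origin = np.asarray(vol.origin)
    rad = hole_radius_mm + spec.wall_thickness_mm
    blo = np.maximum(np.floor((center - rad - origin) / spacing).astype(int), 0)
    bhi = np.minimum(np.ceil((center + rad - origin) / spacing).astype(int) + 1, shape)
    sl = tuple(slice(l, h) for l, h in zip(blo, bhi))
    zz = (np.arange(blo[0], bhi[0]) * spacing[0] + origin[0])[:, None, None]
    yy = (np.arange(blo[1], bhi[1]) * spacing[1] + origin[1])[None, :, None]
    xx = (np.arange(blo[2], bhi[2]) * spacing[2] + origin[2])[None, None, :]
    d2 = (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2
    data = vol.data.copy()
    block = data[sl]
    # clear the full ball (wall plus a little parenchyma) so lumen air
    # connects to parenchyma air through the defect
    hole = d2 <= rad ** 2
    block[hole] = spec.hu_lumen
    data[sl] = block
    return VolumeImage(data, vol.spacing, vol.origin)


def corrupt_segmentation(bundle: PhantomBundle, drop_generations_above: int,
                         leak_blobs: int = 0, leak_voxels_each: int = 10,
                         seed: int = 0) -> BinaryMask:
    """Manufacture a known-imperfect segmentation from a phantom.

    All lumen voxels belonging to branches of generation >
    ``drop_generations_above`` are removed, then ``leak_blobs`` random
    26-connected blobs of exactly ``leak_voxels_each`` voxels are grown in
    the wrong-labelled region next to the retained surface.  Blobs are kept
    at Chebyshev distance >= 2 from each other so each forms its own
    26-connected leakage component.
    """
    if drop_generations_above < 1:
        raise ParameterError("drop_generations_above must be >= 1")
    ref = bundle.labels
    keep_ids = [bi for bi, g in ref.branch_generation.items()
                if g <= drop_generations_above]
    keep = bundle.lumen_mask.data & np.isin(ref.branch_id, keep_ids)
    out = keep.copy()
    if leak_blobs > 0:
        rng = np.random.default_rng(seed)
        wrong = ref.wrong_mask
        near = ndimage.binary_dilation(keep, structure=_B26, iterations=2) & wrong
        cand = np.argwhere(near)
        if len(cand) == 0:
            raise AirtreeError("no wrong-region voxel adjacent to the retained surface")
        blocked = np.zeros_like(keep)
        placed = 0
        for _ in range(200 * leak_blobs):
            if placed == leak_blobs:
                break
            seed_vox = tuple(cand[rng.integers(len(cand))])
            if blocked[seed_vox] or not wrong[seed_vox]:
                continue
            blob = _grow_blob(seed_vox, leak_voxels_each, wrong & ~blocked, rng)
            if blob is None:
                continue
            for v in blob:
                out[v] = True
            bm = np.zeros_like(keep)
            for v in blob:
                bm[v] = True
            blocked |= ndimage.binary_dilation(bm, structure=_B26)
            placed += 1
        if placed < leak_blobs:
            raise AirtreeError(
                f"could only place {placed}/{leak_blobs} leak blobs without "
                "touching the correct region")
    return bundle.lumen_mask.like(out)


def _grow_blob(seed_vox, n_voxels, allowed, rng):
    """Grow a 26-connected blob of exactly n_voxels inside `allowed`."""
    shape = allowed.shape
    blob = {seed_vox}
    frontier = [seed_vox]
    while len(blob) < n_voxels and frontier:
        v = frontier[int(rng.integers(len(frontier)))]
        nbrs = []
        for dz in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    if dz == dy == dx == 0:
                        continue
                    w = (v[0] + dz, v[1] + dy, v[2] + dx)
                    if (0 <= w[0] < shape[0] and 0 <= w[1] < shape[1]
                            and 0 <= w[2] < shape[2]
                            and w not in blob and allowed[w]):
                        nbrs.append(w)
        if not nbrs:
            frontier.remove(v)
            continue
        w = nbrs[int(rng.integers(len(nbrs)))]
        blob.add(w)
        frontier.append(w)
    if len(blob) != n_voxels:
        return None
    return sorted(blob)
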