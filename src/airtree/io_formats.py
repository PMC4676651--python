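"""Readers and writers for MetaImage volumes and VTK legacy centerlines.

MetaImage (.mhd text header + .raw payload) is the interchange format for
volumes and masks; VTK legacy ASCII polydata (POINTS / LINES with a
``generation`` point-data scalar) carries centerline trees.  The MetaImage
route is backed by SimpleITK; the VTK legacy ASCII dialect is written and
parsed directly (only POINTS, LINES and one integer point-data array are
needed).

Supported MetaImage element types: MET_SHORT, MET_UCHAR, MET_FLOAT,
uncompressed only.  Axis order convention: headers store (x, y, z); the
in-memory containers use (z, y, x).
"""

from __future__ import annotations

import os

import numpy as np
import SimpleITK as sitk

from .core import BinaryMask, DataError, VolumeImage
from .tree import Branch, CenterlineTree, tree_from_point_graph, validate_tree

_SUPPORTED_MET_TYPES = {"MET_SHORT", "MET_UCHAR", "MET_FLOAT"}


def _parse_mhd_header(path: str) -> dict[str, str]:
    header = {}
    with open(path, "r") as fh:
        for line in fh:
            if "=" not in line:
                continue
            key, _, value = line.partition("=")
            header[key.strip()] = value.strip()
    return header


def read_metaimage(path: str) -> VolumeImage:
    """Read an uncompressed MetaImage volume (.mhd + .raw).

    Returns a :class:`VolumeImage` (or HU-valued grid) with spacing and
    origin reordered to (z, y, x).  Raises :class:`DataError` for a missing
    raw payload, compressed data, or an element type other than MET_SHORT /
    MET_UCHAR / MET_FLOAT.
    """
    if not os.path.exists(path):
        raise DataError(f"no such MetaImage header: {path}")
    header = _parse_mhd_header(path)
    etype = header.get("ElementType", "")
    if etype not in _SUPPORTED_MET_TYPES:
        raise DataError(f"unsupported MetaImage element type: {etype!r}")
    if header.get("CompressedData", "False").lower() == "true":
        raise DataError("compressed MetaImage data is not supported")
    raw = header.get("ElementDataFile", "")
    if raw and raw.upper() != "LOCAL":
        raw_path = os.path.join(os.path.dirname(path) or ".", raw)
        if not os.path.exists(raw_path):
            raise DataError(f"raw payload not found: {raw_path}")
    try:
        img = sitk.ReadImage(path)
    except RuntimeError as exc:  # pragma: no cover - sitk error surface
        raise DataError(f"failed to read MetaImage {path}: {exc}") from exc
    data = sitk.GetArrayFromImage(img)           # already (z, y, x)
    spacing = tuple(reversed(img.GetSpacing()))  # (x,y,z) -> (z,y,x)
    origin = tuple(reversed(img.GetOrigin()))
    return VolumeImage(data, spacing, origin)


def write_metaimage(volume: VolumeImage | BinaryMask, path: str) -> None:
    """Write a volume or mask as uncompressed .mhd + .raw.

    Masks are written as 8-bit 0/1 (MET_UCHAR); integer volumes as
    MET_SHORT; floating-point volumes as MET_FLOAT.
    """
    if isinstance(volume, BinaryMask):
        data = volume.data.astype(np.uint8)
    elif np.issubdtype(volume.data.dtype, np.floating):
        data = volume.data.astype(np.float32)
    else:
        data = volume.data.astype(np.int16)
    img = sitk.GetImageFromArray(data)
    img.SetSpacing(tuple(reversed(volume.spacing)))
    img.SetOrigin(tuple(reversed(volume.origin)))
    try:
        sitk.WriteImage(img, path, useCompression=False)
    except RuntimeError as exc:
        raise DataError(f"failed to write MetaImage {path}: {exc}") from exc


def read_mask(path: str) -> BinaryMask:
    """Read a MetaImage and binarize it (nonzero voxels true)."""
    v = read_metaimage(path)
    return BinaryMask(v.data != 0, v.spacing, v.origin)


# ---------------------------------------------------------------------------
# VTK legacy ASCII polydata


def write_centerline_polydata(tree: CenterlineTree, path: str) -> None:
    """Write a centerline tree as VTK legacy ASCII polydata.

    One polyline per branch; child branches reference the parent's last
    point index at the bifurcation, so junction points are stored once.
    A ``generation`` point-data scalar stores the branch generation of the
    branch that introduced each point.  VTK point order is (x, y, z).
    """
    if tree is None or not tree.branches:
        raise DataError("refusing to write an empty centerline tree")
    validate_tree(tree)
    points: list[np.ndarray] = []
    gens: list[int] = []
    lines: list[list[int]] = []
    last_index: list[int] = []  # per branch, global index of its last point
    for b in tree.branches:
        idx: list[int] = []
        pts = b.points
        start = 0
        if b.parent is not None:
            idx.append(last_index[b.parent])
            start = 1
        for p in pts[start:]:
            idx.append(len(points))
            points.append(p)
            gens.append(b.generation)
        lines.append(idx)
        last_index.append(idx[-1])

    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("airway centerline tree\n")
        fh.write("ASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {len(points)} float\n")
        for p in points:  # (z,y,x) -> x y z
            fh.write(f"{p[2]:.6f} {p[1]:.6f} {p[0]:.6f}\n")
        size = sum(len(l) + 1 for l in lines)
        fh.write(f"LINES {len(lines)} {size}\n")
        for l in lines:
            fh.write(" ".join(str(i) for i in [len(l)] + l) + "\n")
        fh.write(f"POINT_DATA {len(points)}\n")
        fh.write("SCALARS generation int 1\nLOOKUP_TABLE default\n")
        fh.write("\n".join(str(g) for g in gens) + "\n")


def read_centerline_polydata(path: str) -> CenterlineTree:
    """Read a VTK legacy ASCII polydata centerline into a tree.

    Branch polylines are reassembled into a point graph and re-rooted at
    the maximum-z endpoint (the cranial end of the trachea); generations
    are recomputed from the topology.
    """
    if not os.path.exists(path):
        raise DataError(f"no such polydata file: {path}")
    with open(path, "r") as fh:
        tokens_by_line = [line.split() for line in fh]

    points = None
    connectivity: list[list[int]] = []
    i = 0
    while i < len(tokens_by_line):
        tok = tokens_by_line[i]
        if tok and tok[0].upper() == "POINTS":
            n = int(tok[1])
            flat: list[float] = []
            i += 1
            while len(flat) < 3 * n:
                flat.extend(float(t) for t in tokens_by_line[i])
                i += 1
            xyz = np.asarray(flat).reshape(n, 3)
            points = xyz[:, ::-1]  # x y z -> (z, y, x)
            continue
        if tok and tok[0].upper() == "LINES":
            ncells = int(tok[1])
            i += 1
            vals: list[int] = []
            need = int(tok[2])
            while len(vals) < need:
                vals.extend(int(t) for t in tokens_by_line[i])
                i += 1
            k = 0
            for _ in range(ncells):
                cnt = vals[k]
                connectivity.append(vals[k + 1: k + 1 + cnt])
                k += 1 + cnt
            continue
        i += 1
    if points is None:
        raise DataError(f"polydata without POINTS: {path}")
    if not connectivity:
        raise DataError(f"polydata without LINES: {path}")

    if len(points) == 1:
        return CenterlineTree([Branch(points, 1, None)])
    edges = []
    for poly in connectivity:
        for a, b in zip(poly[:-1], poly[1:]):
            edges.append((a, b))
    # root: endpoint (graph degree 1) with maximal z
    deg = np.zeros(len(points), dtype=int)
    for a, b in edges:
        deg[a] += 1
        deg[b] += 1
    endpoints = np.flatnonzero(deg == 1)
    if len(endpoints) == 0:
        raise DataError("centerline polydata graph has no endpoint to root at")
    root = int(endpoints[np.argmax(points[endpoints, 0])])
    tree = tree_from_point_graph(points, edges, root)
    validate_tree(tree)
    return tree
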