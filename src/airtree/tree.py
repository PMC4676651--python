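"""Rooted centerline trees decomposed into branches with generation indices.

A branch is a maximal centerline path between junction and/or terminal
points.  The trachea is generation 1, the two main bronchi generation 2,
and the generation increments at every junction.  A non-root branch starts
at exactly the last point of its parent (the shared junction point), so a
point at a bifurcation belongs to the parent and to each child polyline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import AirtreeError, DataError


@dataclass
class Branch:
    """One airway branch: an ordered polyline from its proximal junction to
    its distal end, in world mm (z, y, x)."""

    points: np.ndarray          # (k, 3) float, k >= 1
    generation: int = 1
    parent: int | None = None   # index of the parent branch in the tree

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if len(self.points) < 1:
            raise DataError("branch needs at least one point")

    @property
    def length_mm(self) -> float:
        if len(self.points) < 2:
            return 0.0
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())


@dataclass
class CenterlineTree:
    """A rooted, acyclic collection of branches; branch 0 is the root branch."""

    branches: list[Branch] = field(default_factory=list)

    @property
    def root(self) -> np.ndarray:
        """Start point of the generation-1 branch (cranial end of the trachea)."""
        return self.branches[0].points[0]

    @property
    def n_branches(self) -> int:
        return len(self.branches)

    @property
    def max_generation(self) -> int:
        return max(b.generation for b in self.branches)

    def all_points(self) -> np.ndarray:
        """All branch points stacked, (N, 3), junction points repeated."""
        return np.vstack([b.points for b in self.branches])

    def children_of(self, i: int) -> list[int]:
        return [j for j, b in enumerate(self.branches) if b.parent == i]

    def subtree_to_generation(self, max_generation: int) -> "CenterlineTree":
        """Restriction to branches of generation <= max_generation."""
        keep = [i for i, b in enumerate(self.branches) if b.generation <= max_generation]
        remap = {old: new for new, old in enumerate(keep)}
        out = []
        for old in keep:
            b = self.branches[old]
            parent = None if b.parent is None else remap[b.parent]
            out.append(Branch(b.points.copy(), b.generation, parent))
        return CenterlineTree(out)


def validate_tree(tree: CenterlineTree, tol: float = 1e-6) -> None:
    """Check the structural invariants; raise :class:`AirtreeError` on failure.

    Verified: exactly one root branch at generation 1, each child's
    generation is its parent's plus one, each non-root branch starts at its
    parent's last point, the parent links form a connected acyclic forest of
    size one, and branch lengths are finite and non-negative.
    """
    if not tree.branches:
        raise AirtreeError("empty tree")
    roots = [i for i, b in enumerate(tree.branches) if b.parent is None]
    if roots != [0]:
        raise AirtreeError(f"expected exactly branch 0 as root, got roots {roots}")
    if tree.branches[0].generation != 1:
        raise AirtreeError("root branch must be generation 1")
    for i, b in enumerate(tree.branches):
        if b.parent is not None:
            p = tree.branches[b.parent]
            if b.parent >= i:
                raise AirtreeError("branches must be topologically ordered (parent before child)")
            if b.generation != p.generation + 1:
                raise AirtreeError(
                    f"branch {i}: generation {b.generation} != parent generation {p.generation} + 1")
            if np.linalg.norm(b.points[0] - p.points[-1]) > tol:
                raise AirtreeError(f"branch {i} does not start at its parent's last point")
        if not np.all(np.isfinite(b.points)):
            raise AirtreeError(f"branch {i} has non-finite points")
    # parent-before-child ordering plus a single root implies connectivity
    # and acyclicity of the branch graph.


def tree_from_point_graph(points: np.ndarray,
                          edges: list[tuple[int, int]],
                          root_index: int) -> CenterlineTree:
    """Build a branch-decomposed tree from an undirected acyclic point graph.

    Parameters
    ----------
    points : (N, 3) world-mm positions.
    edges : undirected edges (i, j) between point indices; must form a tree.
    root_index : index of the root point (cranial trachea end).

    Junctions (degree >= 3) and the root/leaves delimit branches; children
    at a junction all receive ``parent generation + 1``, also when the
    junction has more than two children.  Neighbor order is sorted for
    determinism.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    n = len(points)
    adj: list[list[int]] = [[] for _ in range(n)]
    for i, j in edges:
        adj[i].append(j)
        adj[j].append(i)
    for a in adj:
        a.sort()
    if n == 1:
        return CenterlineTree([Branch(points[[0]], 1, None)])

    branches: list[Branch] = []
    # stack entries: (start point, first step point, parent branch idx, generation)
    stack: list[tuple[int, int, int | None, int]] = []
    for nb in reversed(adj[root_index]):
        stack.append((root_index, nb, None, 1))
    visited = np.zeros(n, dtype=bool)
    visited[root_index] = True
    while stack:
        start, step, parent, gen = stack.pop()
        path = [start, step]
        visited[step] = True
        prev, cur = start, step
        while True:
            nxt = [k for k in adj[cur] if k != prev and not visited[k]]
            if len(adj[cur]) >= 3 or len(nxt) == 0:
                break  # junction or leaf terminates the branch
            prev, cur = cur, nxt[0]
            visited[cur] = True
            path.append(cur)
        branches.append(Branch(points[path], gen, parent))
        bidx = len(branches) - 1
        for k in reversed([k for k in adj[cur] if not visited[k]]):
            stack.append((cur, k, bidx, gen + 1))
            visited[k] = True  # reserve: each junction child starts one branch
    # the reservation above marks the first step of each pending branch;
    # unmark is unnecessary because a tree graph visits each point once.
    return CenterlineTree(branches)
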