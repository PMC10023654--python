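"""Neuron morphometry from SWC reconstructions.

Total dendritic branch length (TDBL), branch counts, and 3-D Sholl profiles
(intersections of the dendritic arbor with concentric spheres centred on the
soma, 10-um radius steps).  SWC is the standard 7-column reconstruction
format: id, type, x, y, z, radius, parent (parent -1 marks the root).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "NeuronTree",
    "ShollProfile",
    "read_swc",
    "write_swc",
    "tdbl",
    "branch_count",
    "sholl",
]

SOMA_TYPE = 1


@dataclass
class NeuronTree:
    """Rooted reconstruction: node table with parent links.

    ``ids``, ``types``, ``parents`` are int arrays; ``xyz`` is (n, 3) in um.
    Exactly one node has parent -1 (the soma root); parent links must be
    acyclic and refer to existing ids.
    """

    ids: np.ndarray
    types: np.ndarray
    xyz: np.ndarray
    radii: np.ndarray
    parents: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=int)
        self.types = np.asarray(self.types, dtype=int)
        self.xyz = np.asarray(self.xyz, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        self.parents = np.asarray(self.parents, dtype=int)
        self._validate()

    def _validate(self) -> None:
        if len(set(self.ids.tolist())) != len(self.ids):
            raise ValueError("duplicate node ids")
        id_to_idx = {int(i): k for k, i in enumerate(self.ids)}
        roots = np.flatnonzero(self.parents == -1)
        if len(roots) != 1:
            raise ValueError(f"expected exactly one root, found {len(roots)}")
        for nid, pid in zip(self.ids, self.parents):
            if pid == -1:
                continue
            if int(pid) not in id_to_idx:
                raise ValueError(f"node {nid}: parent {pid} does not exist")
        # cycle check by walking every node to the root
        for nid in self.ids:
            seen = set()
            cur = int(nid)
            while cur != -1:
                if cur in seen:
                    raise ValueError(f"cycle detected at node {cur}")
                seen.add(cur)
                cur = int(self.parents[id_to_idx[cur]])
        self._id_to_idx = id_to_idx
        self._root_idx = int(roots[0])

    @property
    def n_nodes(self) -> int:
        return len(self.ids)

    @property
    def soma_xyz(self) -> np.ndarray:
        """Sphere centre for Sholl: centroid of soma-type nodes (falls back
        to the root node when no node is marked as soma)."""
        mask = self.types == SOMA_TYPE
        if mask.any():
            return self.xyz[mask].mean(axis=0)
        return self.xyz[self._root_idx]

    def edges(self) -> np.ndarray:
        """(m, 2) child/parent index pairs for every non-root node."""
        child = np.flatnonzero(self.parents != -1)
        parent = np.array([self._id_to_idx[int(p)] for p in self.parents[child]])
        return np.column_stack([child, parent])

    def children_map(self) -> dict[int, list[int]]:
        ch: dict[int, list[int]] = {k: [] for k in range(self.n_nodes)}
        for c, p in self.edges():
            ch[int(p)].append(int(c))
        return ch


@dataclass
class ShollProfile:
    radii_um: np.ndarray
    intersections: np.ndarray
    cell_id: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"cell_id": self.cell_id, "radius_um": self.radii_um,
             "intersections": self.intersections}
        )


def read_swc(path) -> NeuronTree:
    """Parse a standard 7-column SWC file, validating the topology."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 7:
                raise ValueError(f"{path}:{ln}: expected 7 columns, got {len(parts)}")
            rows.append(parts[:7])
    if not rows:
        raise ValueError(f"{path}: empty SWC file")
    arr = np.array(rows, dtype=float)
    return NeuronTree(
        ids=arr[:, 0].astype(int),
        types=arr[:, 1].astype(int),
        xyz=arr[:, 2:5],
        radii=arr[:, 5],
        parents=arr[:, 6].astype(int),
        name=str(path),
    )


def write_swc(tree: NeuronTree, path) -> None:
    with open(path, "w") as fh:
        fh.write("# id type x y z radius parent\n")
        for i in range(tree.n_nodes):
            x, y, z = tree.xyz[i]
            fh.write(
                f"{tree.ids[i]} {tree.types[i]} {x:.6f} {y:.6f} {z:.6f} "
                f"{tree.radii[i]:.6f} {tree.parents[i]}\n"
            )


def _edge_lengths(tree: NeuronTree, edges: np.ndarray) -> np.ndarray:
    return np.linalg.norm(tree.xyz[edges[:, 0]] - tree.xyz[edges[:, 1]], axis=1)


def _dendrite_edges(tree: NeuronTree) -> np.ndarray:
    """Edges belonging to the arbor: both-endpoints-soma edges excluded."""
    edges = tree.edges()
    if edges.size == 0:
        return edges
    soma_edge = (tree.types[edges[:, 0]] == SOMA_TYPE) & (
        tree.types[edges[:, 1]] == SOMA_TYPE
    )
    return edges[~soma_edge]


def tdbl(tree: NeuronTree) -> float:
    """Total dendritic branch length: sum of Euclidean edge lengths (um)."""
    edges = _dendrite_edges(tree)
    if edges.size == 0:
        return 0.0
    return float(_edge_lengths(tree, edges).sum())


def branch_count(tree: NeuronTree) -> int:
    """Number of dendritic branches.

    A branch is a maximal unbranched path between topological events (soma,
    branch point, terminal tip).  The primary stem leaving the soma counts as
    a branch.
    """
    children = tree.children_map()
    root = tree._root_idx
    n = 0
    # each branch starts at a child of the soma or of a branch point
    stack = [root]
    visited = set()
    while stack:
        node = stack.pop()
        if node in visited:
            continue
        visited.add(node)
        ch = children[node]
        is_event = node == root or len(ch) >= 2
        for c in ch:
            if is_event:
                n += 1  # a new branch starts here
            stack.append(c)
    return n


def _segment_sphere_crossings(a: np.ndarray, b: np.ndarray, center: np.ndarray,
                              r: float) -> int:
    """Number of times segment a->b crosses the sphere of radius r.

    Solves |a + t(b-a) - c|^2 = r^2 on t in (0, 1].  Transversal roots count
    once each; a tangency (double root) counts as a single crossing.  Roots at
    t = 0 are attributed to the previous segment of the polyline so a vertex
    lying exactly on the sphere is not double-counted.
    """
    d = b - a
    f = a - center
    A = float(d @ d)
    B = 2.0 * float(f @ d)
    C = float(f @ f) - r * r
    if A == 0.0:
        return 0
    disc = B * B - 4.0 * A * C
    if disc < 0:
        return 0
    sq = np.sqrt(disc)
    t1 = (-B - sq) / (2.0 * A)
    t2 = (-B + sq) / (2.0 * A)
    if disc == 0.0:
        return 1 if 0.0 < t1 <= 1.0 else 0
    return sum(1 for t in (t1, t2) if 0.0 < t <= 1.0)


def sholl(tree: NeuronTree, step_um: float = 10.0, mode: str = "3d") -> ShollProfile:
    """Sholl profile: arbor/sphere intersection counts at 10-um radius steps.

    ``mode="2d"`` uses concentric circles in the XY plane (thin-slice
    comparisons); default is true 3-D spheres.
    """
    center = tree.soma_xyz
    edges = _dendrite_edges(tree)
    if edges.size == 0:
        return ShollProfile(radii_um=np.array([step_um]),
                            intersections=np.array([0]), cell_id=tree.name)
    if mode == "2d":
        pts = tree.xyz[:, :2]
        c = center[:2]
    elif mode == "3d":
        pts = tree.xyz
        c = center
    else:
        raise ValueError(f"mode must be '2d' or '3d', got {mode!r}")
    dists = np.linalg.norm(pts - c, axis=1)
    r_max = float(dists.max())
    n_shells = max(1, int(np.ceil(r_max / step_um)))
    radii = step_um * np.arange(1, n_shells + 1)
    counts = np.zeros(n_shells, dtype=int)
    for child, parent in edges:
        a, b = pts[parent], pts[child]
        # d(t) along a segment is maximal at an endpoint, so no shell beyond
        # the farther endpoint can be crossed
        hi = max(dists[parent], dists[child])
        for k, r in enumerate(radii):
            if r > hi:
                break
            counts[k] += _segment_sphere_crossings(a, b, c, float(r))
    return ShollProfile(radii_um=radii, intersections=counts, cell_id=tree.name)
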