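"""Icosahedral sphere hierarchy and the parent/child maps that define pooling.

The icosphere is the recursive 1-to-4 subdivision of a regular icosahedron:
each subdivision inserts one new node at the midpoint of every unique edge
(re-projected onto the unit sphere) and splits every triangle into four.
Node counts follow 12, 42, 162, 642, 2562, 10242, 40962, ... = 10*4^L + 2.

Conventions
-----------
* The base icosahedron uses the golden-ratio construction: the 12 vertices
  are the cyclic permutations of (0, +-1, +-phi), normalized to unit length.
  The z-axis is the pole; patch placement aligns filter grids with the local
  east (latitude) direction relative to this axis.
* Subdivision preserves parent-node indices as a prefix of the child mesh
  ("prefix property"), so level-k node i and level-(k+1) node i coincide.
* New nodes are appended in sorted (min-index, max-index) edge order, making
  the whole hierarchy bit-reproducible.
* All node and triangle indices are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

__all__ = [
    "IcosphereMesh",
    "PoolingMap",
    "base_icosahedron",
    "subdivide",
    "icosphere",
    "pooling_map",
]

# Node counts 12, 42, ..., 40962 for levels 0..6.
NODE_COUNTS = tuple(10 * 4**k + 2 for k in range(7))


@dataclass(frozen=True)
class IcosphereMesh:
    """A subdivided icosahedral mesh on the unit sphere.

    Attributes
    ----------
    level : int
        Number of subdivisions applied to the base icosahedron.
    nodes : (N, 3) float64 array
        Unit-norm node coordinates.
    triangles : (T, 3) int array
        Node-index triples, T = 20 * 4**level.
    """

    level: int
    nodes: np.ndarray
    triangles: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_triangles(self) -> int:
        return self.triangles.shape[0]

    def edges(self) -> np.ndarray:
        """Unique undirected edges as a sorted (E, 2) int array."""
        t = self.triangles
        e = np.concatenate([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
        e = np.sort(e, axis=1)
        return np.unique(e, axis=0)

    def neighbors(self) -> list[np.ndarray]:
        """1-ring neighbor indices of every node, each sorted ascending."""
        e = self.edges()
        adj: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for a, b in e:
            adj[a].append(b)
            adj[b].append(a)
        return [np.array(sorted(v), dtype=np.int64) for v in adj]

    def mean_edge_angle(self) -> float:
        """Mean angular length (radians) of the 1-ring edges.

        Used as the default spacing of rectangular/circular filter patches,
        so a 5x5 patch spans about four inter-node distances.
        """
        e = self.edges()
        d = np.einsum("ij,ij->i", self.nodes[e[:, 0]], self.nodes[e[:, 1]])
        return float(np.mean(np.arccos(np.clip(d, -1.0, 1.0))))


@dataclass(frozen=True)
class PoolingMap:
    """Parent/child relation between consecutive icosphere levels.

    ``children[c]`` lists the fine-level nodes averaged into coarse node c
    (the coarse node itself plus its fine-level 1-ring, when ``include_self``).
    ``multiplicity[j]`` counts how many coarse parents fine node j feeds;
    it is needed by the backward (error-distribution) rule.
    """

    coarse_level: int
    fine_level: int
    children: tuple[np.ndarray, ...]
    multiplicity: np.ndarray
    include_self: bool = True
    _matrix: sp.csr_matrix | None = field(default=None, repr=False, compare=False)

    @property
    def n_coarse(self) -> int:
        return len(self.children)

    @property
    def n_fine(self) -> int:
        return self.multiplicity.shape[0]

    def matrix(self) -> sp.csr_matrix:
        """Sparse (n_coarse, n_fine) averaging matrix; rows sum to 1.

        Forward pooling is ``A @ x``; the exact adjoint ``A.T @ g`` realises
        the equal-distribution backward rule (each parent's error divided by
        its child count, summed over a fine node's parents).
        """
        rows = np.concatenate(
            [np.full(len(ch), c, dtype=np.int64) for c, ch in enumerate(self.children)]
        )
        cols = np.concatenate(self.children)
        vals = np.concatenate(
            [np.full(len(ch), 1.0 / len(ch)) for ch in self.children]
        )
        return sp.csr_matrix(
            (vals, (rows, cols)), shape=(self.n_coarse, self.n_fine)
        )


def base_icosahedron() -> IcosphereMesh:
    """The regular icosahedron: 12 unit-norm nodes, 20 triangles, 30 edges."""
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = []
    for a, b in [(1.0, phi)]:
        for s1 in (+1, -1):
            for s2 in (+1, -1):
                verts.append((0.0, s1 * a, s2 * b))       # (0, ±1, ±φ)
                verts.append((s1 * a, s2 * b, 0.0))       # (±1, ±φ, 0)
                verts.append((s2 * b, 0.0, s1 * a))       # (±φ, 0, ±1)
    nodes = np.array(verts, dtype=np.float64)
    nodes /= np.linalg.norm(nodes, axis=1, keepdims=True)

    # Faces: every vertex triple that is pairwise at the minimal (edge)
    # distance. Deterministic lexicographic order.
    d2 = np.sum((nodes[:, None, :] - nodes[None, :, :]) ** 2, axis=-1)
    edge2 = np.min(d2[d2 > 1e-9])
    adj = np.abs(d2 - edge2) < 1e-9
    tris = []
    for i in range(12):
        for j in range(i + 1, 12):
            if not adj[i, j]:
                continue
            for k in range(j + 1, 12):
                if adj[i, k] and adj[j, k]:
                    tris.append((i, j, k))
    triangles = np.array(tris, dtype=np.int64)
    assert triangles.shape == (20, 3)
    return IcosphereMesh(level=0, nodes=nodes, triangles=triangles)


def subdivide(mesh: IcosphereMesh) -> IcosphereMesh:
    """One 1-to-4 subdivision: a new node at each unique edge midpoint.

    Midpoints are re-projected onto the unit sphere. Parent nodes keep their
    indices; new nodes are appended in sorted (min, max) edge order.
    """
    n = mesh.n_nodes
    edges = mesh.edges()  # already sorted lexicographically by np.unique
    mids = mesh.nodes[edges[:, 0]] + mesh.nodes[edges[:, 1]]
    mids /= np.linalg.norm(mids, axis=1, keepdims=True)
    nodes = np.vstack([mesh.nodes, mids])

    # edge (a, b) -> index of its midpoint node
    edge_id = {(int(a), int(b)): n + i for i, (a, b) in enumerate(edges)}

    def mid(a: int, b: int) -> int:
        return edge_id[(a, b) if a < b else (b, a)]

    tris = np.empty((4 * mesh.n_triangles, 3), dtype=np.int64)
    for t, (a, b, c) in enumerate(mesh.triangles):
        a, b, c = int(a), int(b), int(c)
        mab, mbc, mca = mid(a, b), mid(b, c), mid(c, a)
        tris[4 * t : 4 * t + 4] = [
            (a, mab, mca),
            (b, mbc, mab),
            (c, mca, mbc),
            (mab, mbc, mca),
        ]
    return IcosphereMesh(level=mesh.level + 1, nodes=nodes, triangles=tris)


def icosphere(level: int) -> IcosphereMesh:
    """Base icosahedron subdivided ``level`` times; 10*4**level + 2 nodes."""
    if level < 0:
        raise ValueError(f"subdivision level must be >= 0, got {level}")
    mesh = base_icosahedron()
    for _ in range(level):
        mesh = subdivide(mesh)
    return mesh


def pooling_map(
    fine: IcosphereMesh, coarse: IcosphereMesh, include_self: bool = True
) -> PoolingMap:
    """Parent/child map for mean pooling from ``fine`` down to ``coarse``.

    Each coarse node's children are itself (under fine indexing, by the
    prefix property) plus its fine-level 1-ring neighbors. With
    ``include_self=False`` the parent's own fine value is excluded from the
    average.
    """
    if coarse.level != fine.level - 1:
        raise ValueError(
            f"coarse level must be fine level - 1, got {coarse.level} and {fine.level}"
        )
    nb = fine.neighbors()
    nc = coarse.n_nodes
    children = []
    for c in range(nc):
        ch = np.concatenate([[c], nb[c]]) if include_self else nb[c]
        children.append(np.asarray(ch, dtype=np.int64))
    multiplicity = np.zeros(fine.n_nodes, dtype=np.int64)
    for ch in children:
        multiplicity[ch] += 1
    return PoolingMap(
        coarse_level=coarse.level,
        fine_level=fine.level,
        children=tuple(children),
        multiplicity=multiplicity,
        include_self=include_self,
    )
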