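"""Filter-patch geometry on the sphere and the gather that builds the
full-node filter point matrix I.

Mesh convolution is recast as plain matrix multiplication: for every node n
a small patch of P filter points is placed on the sphere around n, each
point is snapped to its nearest mesh node, and the sampled values form row n
of an N x P matrix I. Multiplying I by a length-P weight vector then
convolves the whole surface at once.

Three patch geometries are supported:

* rectangular — an Sx x Sy planar grid (origin-centered, odd side lengths);
* circular    — concentric rings of equally spaced points around the origin;
* polygonal   — the node's own graph neighborhood up to order R (no planar
  geometry involved).

Planar patches are mapped to the sphere with the azimuthal-equidistant
(exponential-map) projection: a planar point at distance d and bearing theta
lands at geodesic distance d radians from the patch origin along bearing
theta. The patch x-axis is aligned with the local east direction
(z x n / |z x n|), i.e. "along the geographical latitude"; at the two poles,
where east is undefined, the global x-axis is used.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .icosphere import IcosphereMesh

__all__ = [
    "PatchTemplate",
    "SamplingMap",
    "FilterPointMatrix",
    "rectangular_template",
    "circular_template",
    "polygonal_neighbors",
    "place_patch",
    "build_sampling_map",
    "sample",
    "save_sampling_map",
    "load_sampling_map",
]


@dataclass(frozen=True)
class PatchTemplate:
    """Planar geometry of one filter patch before per-node placement.

    ``points`` holds (P, 2) planar offsets in radians of geodesic distance,
    origin point first.
    """

    kind: str  # "rectangular" | "circular"
    points: np.ndarray
    params: tuple

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    def cache_key(self) -> str:
        return f"{self.kind}-" + "-".join(repr(p) for p in self.params)


@dataclass(frozen=True)
class SamplingMap:
    """Per-node filter-point -> mesh-node index table.

    ``index[n, p]`` is the mesh node nearest to filter point p of node n's
    patch. Polygonal patches with ragged neighborhoods are padded with the
    sentinel index ``n_nodes``; sampled values at the sentinel are 0 and it
    receives no gradient.
    """

    mesh_level: int
    n_nodes: int
    index: np.ndarray  # (N, P) int64, entries in [0, n_nodes]
    kind: str
    params: tuple

    @property
    def n_points(self) -> int:
        return self.index.shape[1]

    @property
    def sentinel(self) -> int:
        return self.n_nodes

    @property
    def has_padding(self) -> bool:
        return bool(np.any(self.index == self.n_nodes))


@dataclass(frozen=True)
class FilterPointMatrix:
    """Sampled surface values, shape (N, P, C); the matrix I of the model."""

    values: np.ndarray
    provenance: SamplingMap


def rectangular_template(sx: int, sy: int, spacing: float) -> PatchTemplate:
    """Origin-centered Sx x Sy grid with the given angular spacing (radians).

    Point 0 is the origin; the remaining points follow in row-major order
    (y from top to bottom, x left to right).
    """
    if sx % 2 == 0 or sy % 2 == 0 or sx < 1 or sy < 1:
        raise ValueError(f"Sx and Sy must be odd positive integers, got {sx}x{sy}")
    if spacing <= 0:
        raise ValueError(f"spacing must be positive, got {spacing}")
    xs = (np.arange(sx) - sx // 2) * spacing
    ys = (np.arange(sy) - sy // 2) * spacing
    gx, gy = np.meshgrid(xs, -ys, indexing="xy")
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    origin = sx * sy // 2  # center of the row-major grid
    order = np.concatenate([[origin], np.delete(np.arange(sx * sy), origin)])
    return PatchTemplate("rectangular", pts[order], (sx, sy, float(spacing)))


def circular_template(
    n_rings: int, points_per_ring: int, ring_spacing: float
) -> PatchTemplate:
    """Origin plus ``n_rings`` concentric rings; ring r sits at radius
    r * ring_spacing, with ``points_per_ring`` points starting at angle 0."""
    if n_rings < 1:
        raise ValueError(f"n_rings must be >= 1, got {n_rings}")
    if points_per_ring < 3:
        raise ValueError(f"points_per_ring must be >= 3, got {points_per_ring}")
    if ring_spacing <= 0:
        raise ValueError(f"ring_spacing must be positive, got {ring_spacing}")
    pts = [(0.0, 0.0)]
    ang = 2 * np.pi * np.arange(points_per_ring) / points_per_ring
    for r in range(1, n_rings + 1):
        rad = r * ring_spacing
        pts.extend(zip(rad * np.cos(ang), rad * np.sin(ang)))
    return PatchTemplate(
        "circular",
        np.asarray(pts),
        (n_rings, points_per_ring, float(ring_spacing)),
    )


def polygonal_neighbors(mesh: IcosphereMesh, order: int) -> SamplingMap:
    """Graph-neighborhood patches: self, then 1st..R-th order neighbors.

    Each neighbor order is sorted by node index. Rows shorter than the
    longest patch are padded with the sentinel index ``mesh.n_nodes``.
    """
    if order < 1:
        raise ValueError(f"neighbor order must be >= 1, got {order}")
    nb = mesh.neighbors()
    n = mesh.n_nodes
    rows: list[np.ndarray] = []
    for start in range(n):
        seen = {start}
        frontier = [start]
        row = [start]
        for _ in range(order):
            nxt = sorted(
                {int(j) for i in frontier for j in nb[i]} - seen
            )
            row.extend(nxt)
            seen.update(nxt)
            frontier = nxt
        rows.append(np.asarray(row, dtype=np.int64))
    p = max(len(r) for r in rows)
    index = np.full((n, p), n, dtype=np.int64)
    for i, r in enumerate(rows):
        index[i, : len(r)] = r
    return SamplingMap(
        mesh_level=mesh.level,
        n_nodes=n,
        index=index,
        kind="polygonal",
        params=(order,),
    )


def _local_frames(nodes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """East and north tangent unit vectors at each node (z-axis = pole).

    East is z x n normalized; at the poles (|z x n| = 0) the global x-axis
    stands in for east. North completes the right-handed frame as n x east.
    """
    z = np.array([0.0, 0.0, 1.0])
    east = np.cross(np.broadcast_to(z, nodes.shape), nodes)
    norms = np.linalg.norm(east, axis=1)
    polar = norms < 1e-12
    east[polar] = (1.0, 0.0, 0.0)
    norms[polar] = 1.0
    east /= norms[:, None]
    north = np.cross(nodes, east)
    return east, north


def place_patch(
    template: PatchTemplate, mesh: IcosphereMesh, node: int
) -> np.ndarray:
    """Place a planar template on the sphere at one mesh node.

    Azimuthal-equidistant mapping in the node's tangent frame: planar point
    (x, y) at distance d = sqrt(x^2+y^2), bearing theta = atan2(y, x) maps to
    cos(d) n + sin(d) (cos(theta) east + sin(theta) north). Returns (P, 3)
    unit vectors.
    """
    return _place_patches(template, mesh.nodes[node : node + 1], )[0]


def _place_patches(template: PatchTemplate, nodes: np.ndarray) -> np.ndarray:
    """Vectorized placement at many nodes; returns (N, P, 3)."""
    d = np.linalg.norm(template.points, axis=1)  # (P,)
    theta = np.arctan2(template.points[:, 1], template.points[:, 0])
    east, north = _local_frames(nodes)
    tangent = (
        np.cos(theta)[None, :, None] * east[:, None, :]
        + np.sin(theta)[None, :, None] * north[:, None, :]
    )
    pts = (
        np.cos(d)[None, :, None] * nodes[:, None, :]
        + np.sin(d)[None, :, None] * tangent
    )
    return pts / np.linalg.norm(pts, axis=2, keepdims=True)


def default_spacing(mesh: IcosphereMesh) -> float:
    """Default patch spacing: the mesh's mean 1-ring angular edge length."""
    return mesh.mean_edge_angle()


def build_sampling_map(
    template: PatchTemplate,
    mesh: IcosphereMesh,
    cache_dir: str | Path | None = None,
) -> SamplingMap:
    """Nearest-node index table for a planar template placed at every node.

    Nearest is by greatest dot product (equivalently smallest chord
    distance); near-ties within 1e-12 chord distance break to the lowest
    node index. The map depends only on (template, mesh level) and can be
    cached to ``cache_dir`` as HDF5.
    """
    if cache_dir is not None:
        cache_dir = Path(cache_dir)
        digest = hashlib.sha1(
            f"L{mesh.level}-{template.cache_key()}".encode()
        ).hexdigest()[:16]
        path = cache_dir / f"sampling-{digest}.h5"
        if path.exists():
            return load_sampling_map(path)

    placed = _place_patches(template, mesh.nodes)  # (N, P, 3)
    n, p, _ = placed.shape
    tree = cKDTree(mesh.nodes)
    dist, idx = tree.query(placed.reshape(-1, 3), k=2)
    # break near-ties to the lowest index
    tie = dist[:, 1] - dist[:, 0] < 1e-12
    best = idx[:, 0].copy()
    best[tie] = np.min(idx[tie], axis=1)
    smap = SamplingMap(
        mesh_level=mesh.level,
        n_nodes=n,
        index=best.reshape(n, p).astype(np.int64),
        kind=template.kind,
        params=template.params,
    )
    if cache_dir is not None:
        cache_dir.mkdir(parents=True, exist_ok=True)
        save_sampling_map(smap, path)
    return smap


def sample(smap: SamplingMap, surface_values: np.ndarray) -> FilterPointMatrix:
    """Gather surface values through the sampling map: I[n, p, c].

    ``surface_values`` is (N,) or (N, C); padded (sentinel) entries yield 0.
    """
    v = np.asarray(surface_values, dtype=np.float64)
    if v.ndim == 1:
        v = v[:, None]
    if v.shape[0] != smap.n_nodes:
        raise ValueError(
            f"surface has {v.shape[0]} rows, sampling map expects {smap.n_nodes}"
        )
    padded = np.vstack([v, np.zeros((1, v.shape[1]))])  # sentinel row -> 0
    return FilterPointMatrix(values=padded[smap.index], provenance=smap)


def save_sampling_map(smap: SamplingMap, path: str | Path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("index", data=smap.index, compression="gzip")
        f.attrs["mesh_level"] = smap.mesh_level
        f.attrs["n_nodes"] = smap.n_nodes
        f.attrs["kind"] = smap.kind
        f.attrs["params"] = json.dumps(list(smap.params))


def load_sampling_map(path: str | Path) -> SamplingMap:
    import h5py

    with h5py.File(path, "r") as f:
        return SamplingMap(
            mesh_level=int(f.attrs["mesh_level"]),
            n_nodes=int(f.attrs["n_nodes"]),
            index=f["index"][()],
            kind=str(f.attrs["kind"]),
            params=tuple(json.loads(f.attrs["params"])),
        )
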