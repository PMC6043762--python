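"""Data conditioning on the sphere: per-subject demeaning, resampling from an
arbitrary spherical mesh onto the icosphere, and global spherical rotation.

A :class:`SurfaceMap` is one subject's labeled per-node scalar field (e.g.
cortical thickness in mm), with one column per hemisphere channel and a
validity mask marking non-cortical nodes (the medial wall), which are
excluded from statistics and fed to the network as zero.

"Bilinear" interpolation on a triangle mesh is read as barycentric
interpolation — the 2-simplex analogue — computed inside the spherical
triangle containing each target node. Rotation resampling is a nearest-node
pull-back, matching the order-0 interpolation used by patch sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .icosphere import IcosphereMesh

__all__ = [
    "SurfaceMap",
    "SphericalRotation",
    "demean",
    "resample_to_icosphere",
    "rotation_index",
    "rotate_map",
]


@dataclass(frozen=True)
class SurfaceMap:
    """Labeled per-node scalar field for one subject.

    values : (N, C) float array, C hemisphere channels (mm for thickness).
    valid : (N, C) bool array; False marks nodes where the measurement is
        unavailable (medial wall).
    """

    subject_id: str
    label: int
    values: np.ndarray
    valid: np.ndarray
    mesh_level: int

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    def network_input(self) -> np.ndarray:
        """Values with invalid nodes zeroed, ready for the model."""
        return np.where(self.valid, self.values, 0.0)


@dataclass(frozen=True)
class SphericalRotation:
    """Rotation of the sphere about ``axis`` by ``angle`` radians."""

    axis: np.ndarray
    angle: float

    def __post_init__(self):
        a = np.asarray(self.axis, dtype=np.float64)
        n = np.linalg.norm(a)
        if not np.isclose(n, 1.0, atol=1e-9):
            a = a / n
        object.__setattr__(self, "axis", a)

    def matrix(self) -> np.ndarray:
        return Rotation.from_rotvec(self.axis * self.angle).as_matrix()

    def inverse(self) -> "SphericalRotation":
        return SphericalRotation(self.axis, -self.angle)


def demean(smap: SurfaceMap) -> SurfaceMap:
    """Subtract the subject's whole-brain mean (over valid nodes of all
    channels) from every value; one scalar per subject."""
    if not np.any(smap.valid):
        raise ValueError(f"surface map {smap.subject_id!r} has no valid nodes")
    mean = smap.values[smap.valid].mean()
    return replace(smap, values=smap.values - mean)


def _barycentric_lookup(
    points: np.ndarray, src_nodes: np.ndarray, src_triangles: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Containing source triangle and barycentric weights for each point.

    The containing spherical triangle is found among triangles incident to
    the point's nearest source nodes; weights solve p = w1 v1 + w2 v2 + w3 v3
    (central projection onto the triangle plane), normalized to sum 1.
    """
    tree = cKDTree(src_nodes)
    incident: list[list[int]] = [[] for _ in range(len(src_nodes))]
    for t, tri in enumerate(src_triangles):
        for v in tri:
            incident[int(v)].append(t)

    n = len(points)
    tri_of = np.full(n, -1, dtype=np.int64)
    weights = np.zeros((n, 3))
    for i, p in enumerate(points):
        best_t, best_w, best_min = -1, None, -np.inf
        for k in (1, 4, 12):
            _, nn = tree.query(p, k=k)
            nn = np.atleast_1d(nn)
            cand = sorted({t for v in nn for t in incident[int(v)]})
            for t in cand:
                v = src_nodes[src_triangles[t]]
                try:
                    w = np.linalg.solve(v.T, p)
                except np.linalg.LinAlgError as exc:
                    raise ArithmeticError(
                        f"degenerate source triangle {t}"
                    ) from exc
                s = w.sum()
                if abs(s) < 1e-12:
                    continue
                w = w / s
                wm = w.min()
                if wm > best_min:
                    best_t, best_w, best_min = t, w, wm
            if best_min >= -1e-9:
                break
        tri_of[i] = best_t
        weights[i] = np.clip(best_w, 0.0, None)
        weights[i] /= weights[i].sum()
    return tri_of, weights


def resample_to_icosphere(
    values: np.ndarray,
    src_nodes: np.ndarray,
    src_triangles: np.ndarray,
    target: IcosphereMesh,
    valid: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Barycentric resampling from an arbitrary spherical mesh to the
    icosphere.

    Returns (target_values, target_valid), both (N_target, C); a target
    node is invalid in a channel when any vertex of its containing source
    triangle is invalid there.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.ndim == 1:
        values = values[:, None]
    src_nodes = np.asarray(src_nodes, dtype=np.float64)
    src_nodes = src_nodes / np.linalg.norm(src_nodes, axis=1, keepdims=True)
    if valid is None:
        valid = np.ones(values.shape, dtype=bool)
    tri_of, w = _barycentric_lookup(target.nodes, src_nodes, src_triangles)
    tri_verts = src_triangles[tri_of]  # (Nt, 3)
    out = np.einsum("nk,nkc->nc", w, values[tri_verts])
    out_valid = np.all(valid[tri_verts], axis=1)
    return out, out_valid


def rotation_index(mesh: IcosphereMesh, rot: SphericalRotation) -> np.ndarray:
    """Nearest-node pull-back index: rotated[n] = original[index[n]].

    index[n] is the mesh node nearest to rot^-1 applied to node n, so
    gathering through it rotates a map forward by ``rot``.
    """
    back = mesh.nodes @ rot.matrix()  # R^-1 x = x @ R (orthogonal)
    tree = cKDTree(mesh.nodes)
    _, idx = tree.query(back)
    return idx.astype(np.int64)


def rotate_map(
    smap: SurfaceMap, rot: SphericalRotation, mesh: IcosphereMesh
) -> SurfaceMap:
    """Globally rotate a map on the icosphere (nearest-node resampling);
    validity flags are transported identically."""
    idx = rotation_index(mesh, rot)
    return replace(smap, values=smap.values[idx], valid=smap.valid[idx])
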