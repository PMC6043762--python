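"""Reading and writing meshes, per-node scalar maps and subject manifests.

Surface geometry goes to GIFTI ``.surf.gii`` (via nibabel) or plain text
(one "x y z" line per node, then one "i j k" line per triangle, separated
by a blank line). Scalar maps go to GIFTI ``.func.gii``/``.shape.gii`` (one
data array per channel) or plain text with one value per line per channel
file. Manifests are tab-separated: subject_id, label, left_map_path,
right_map_path.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .icosphere import IcosphereMesh
from .transforms import SurfaceMap

__all__ = [
    "write_mesh_gifti",
    "read_mesh_gifti",
    "write_mesh_text",
    "read_mesh_text",
    "write_scalar_gifti",
    "read_scalar_gifti",
    "write_scalar_text",
    "read_scalar_text",
    "read_manifest",
    "write_manifest",
    "load_surface_map",
]

MANIFEST_COLUMNS = ["subject_id", "label", "left_map_path", "right_map_path"]


def write_mesh_gifti(mesh: IcosphereMesh, path: str | Path) -> None:
    import nibabel as nib

    coords = nib.gifti.GiftiDataArray(
        mesh.nodes.astype(np.float32), intent="NIFTI_INTENT_POINTSET"
    )
    tris = nib.gifti.GiftiDataArray(
        mesh.triangles.astype(np.int32), intent="NIFTI_INTENT_TRIANGLE"
    )
    nib.save(nib.gifti.GiftiImage(darrays=[coords, tris]), str(path))


def read_mesh_gifti(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Node coordinates and triangles from a GIFTI surface file."""
    import nibabel as nib

    img = nib.load(str(path))
    coords = tris = None
    for da in img.darrays:
        if da.intent == 1008:  # POINTSET
            coords = np.asarray(da.data, dtype=np.float64)
        elif da.intent == 1009:  # TRIANGLE
            tris = np.asarray(da.data, dtype=np.int64)
    if coords is None or tris is None:
        raise ValueError(f"{path} lacks a POINTSET or TRIANGLE array")
    return coords, tris


def write_mesh_text(mesh: IcosphereMesh, path: str | Path) -> None:
    with open(path, "w") as f:
        for x, y, z in mesh.nodes:
            f.write(f"{x:.17g} {y:.17g} {z:.17g}\n")
        f.write("\n")
        for i, j, k in mesh.triangles:
            f.write(f"{i} {j} {k}\n")


def read_mesh_text(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    nodes, tris = [], []
    section = nodes
    with open(path) as f:
        for line in f:
            line = line.strip()
            if not line:
                section = tris
                continue
            section.append(line.split())
    return (
        np.array(nodes, dtype=np.float64),
        np.array(tris, dtype=np.int64),
    )


def write_scalar_gifti(values: np.ndarray, path: str | Path) -> None:
    """One GIFTI data array per channel column."""
    import nibabel as nib

    v = np.atleast_2d(np.asarray(values, dtype=np.float32).T).T
    darrays = [
        nib.gifti.GiftiDataArray(v[:, c].copy(), intent="NIFTI_INTENT_NONE")
        for c in range(v.shape[1])
    ]
    nib.save(nib.gifti.GiftiImage(darrays=darrays), str(path))


def read_scalar_gifti(path: str | Path) -> np.ndarray:
    import nibabel as nib

    img = nib.load(str(path))
    return np.column_stack([np.asarray(da.data, dtype=np.float64) for da in img.darrays])


def write_scalar_text(values: np.ndarray, path: str | Path) -> None:
    np.savetxt(path, np.asarray(values, dtype=np.float64), fmt="%.17g")


def read_scalar_text(path: str | Path) -> np.ndarray:
    return np.loadtxt(path, dtype=np.float64)


def write_manifest(df: pd.DataFrame, path: str | Path) -> None:
    df[MANIFEST_COLUMNS].to_csv(path, sep="\t", index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} lacks columns {sorted(missing)}")
    return df


def _read_map_file(path: str | Path) -> np.ndarray:
    p = str(path)
    if p.endswith(".gii"):
        return read_scalar_gifti(p)
    return np.atleast_1d(read_scalar_text(p))


def load_surface_map(
    row, mesh_level: int, invalid_value: float = np.nan
) -> SurfaceMap:
    """Build a SurfaceMap from one manifest row (left/right channel files).

    Nodes equal to ``invalid_value`` (NaN by default) are flagged invalid.
    """
    left = _read_map_file(row["left_map_path"]).reshape(-1)
    right = _read_map_file(row["right_map_path"]).reshape(-1)
    values = np.column_stack([left, right])
    if np.isnan(invalid_value):
        valid = ~np.isnan(values)
        values = np.nan_to_num(values)
    else:
        valid = values != invalid_value
    return SurfaceMap(
        subject_id=str(row["subject_id"]),
        label=int(row["label"]),
        values=values,
        valid=valid,
        mesh_level=mesh_level,
    )
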