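"""Morphological (shape) features of the tumor mask: 20 values.

Shape features are the only family that uses physical voxel spacing; they are
computed once per case, independent of the discretization sweep.  Surface
area and mesh volume come from a marching-cubes triangulation of the mask by
default; a voxel-face-counting surface is available via
``surface_method="face"`` (it overestimates curved surfaces and is mainly
useful for rectilinear phantoms).
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist
from skimage import measure

from ..images import TumorMask

SHAPE_FEATURES = (
    "MeshVolume",
    "VoxelVolume",
    "SurfaceArea",
    "SurfaceVolumeRatio",
    "Sphericity",
    "Compactness1",
    "Compactness2",
    "SphericalDisproportion",
    "Maximum3DDiameter",
    "Maximum2DDiameterAxial",
    "Maximum2DDiameterCoronal",
    "Maximum2DDiameterSagittal",
    "MajorAxisLength",
    "MinorAxisLength",
    "LeastAxisLength",
    "Elongation",
    "Flatness",
    "LargestSliceArea",
    "LargestSlicePerimeter",
    "PerimeterToAreaRatio",
)


def _mesh(mask: np.ndarray, spacing: tuple[float, float, float]):
    padded = np.pad(mask, 1).astype(np.float64)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=spacing)
    return verts, faces


def _mesh_volume(verts: np.ndarray, faces: np.ndarray) -> float:
    tri = verts[faces]
    signed = np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])) / 6.0
    return float(abs(signed.sum()))


def _face_count_area(mask: np.ndarray, spacing: tuple[float, float, float]) -> float:
    area = 0.0
    face_areas = (
        spacing[1] * spacing[2],
        spacing[0] * spacing[2],
        spacing[0] * spacing[1],
    )
    padded = np.pad(mask, 1)
    for ax, fa in enumerate(face_areas):
        diff = np.diff(padded.astype(np.int8), axis=ax)
        area += float(np.abs(diff).sum()) * fa
    return area


def _max_pairwise(points: np.ndarray) -> float:
    """Largest pairwise Euclidean distance; convex hull prunes when possible."""
    if len(points) < 2:
        return 0.0
    pts = points
    if len(points) > 12:
        try:
            pts = points[ConvexHull(points).vertices]
        except QhullError:  # degenerate (flat) point sets
            pass
    if len(pts) > 3000:  # pathological fall-back, keeps pdist bounded
        pts = pts[:: len(pts) // 3000 + 1]
    return float(pdist(pts).max())


def _slice_perimeter(sl: np.ndarray, sr: float, sc: float) -> float:
    padded = np.pad(sl, 1).astype(np.int8)
    row_edges = float(np.abs(np.diff(padded, axis=0)).sum())  # edges along cols
    col_edges = float(np.abs(np.diff(padded, axis=1)).sum())  # edges along rows
    return row_edges * sc + col_edges * sr


def shape_features(
    mask: TumorMask,
    spacing: tuple[float, float, float],
    surface_method: str = "mesh",
) -> dict[str, float | None]:
    if surface_method not in ("mesh", "face"):
        raise ValueError(f"surface_method must be 'mesh' or 'face', got {surface_method!r}")
    m = mask.membership
    sp = tuple(float(s) for s in spacing)
    out: dict[str, float | None] = {}

    n_vox = int(m.sum())
    voxel_volume = n_vox * sp[0] * sp[1] * sp[2]
    out["VoxelVolume"] = voxel_volume

    verts, faces = _mesh(m, sp)
    mesh_volume = _mesh_volume(verts, faces)
    out["MeshVolume"] = mesh_volume
    if surface_method == "mesh":
        area = float(measure.mesh_surface_area(verts, faces))
        vol = mesh_volume
    else:
        area = _face_count_area(m, sp)
        vol = voxel_volume
    out["SurfaceArea"] = area
    out["SurfaceVolumeRatio"] = area / vol if vol > 0 else None

    if vol > 0 and area > 0:
        out["Sphericity"] = float(np.pi ** (1 / 3) * (6 * vol) ** (2 / 3) / area)
        out["Compactness1"] = float(vol / (np.sqrt(np.pi) * area ** 1.5))
        out["Compactness2"] = float(36 * np.pi * vol**2 / area**3)
        radius = (3 * vol / (4 * np.pi)) ** (1 / 3)
        out["SphericalDisproportion"] = float(area / (4 * np.pi * radius**2))
    else:
        for name in ("Sphericity", "Compactness1", "Compactness2", "SphericalDisproportion"):
            out[name] = None

    coords = np.argwhere(m).astype(np.float64) * np.asarray(sp)
    out["Maximum3DDiameter"] = _max_pairwise(coords)
    out["Maximum2DDiameterAxial"] = _max_pairwise(coords[:, 1:])  # rows x cols
    out["Maximum2DDiameterCoronal"] = _max_pairwise(coords[:, [0, 2]])
    out["Maximum2DDiameterSagittal"] = _max_pairwise(coords[:, [0, 1]])

    if len(coords) >= 2:
        cov = np.cov(coords, rowvar=False, ddof=0)
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        eig = np.clip(eig, 0.0, None)
        out["MajorAxisLength"] = float(4 * np.sqrt(eig[0])) if eig[0] > 0 else None
        out["MinorAxisLength"] = float(4 * np.sqrt(eig[1])) if eig[1] > 0 else None
        out["LeastAxisLength"] = float(4 * np.sqrt(eig[2])) if eig[2] > 0 else None
        out["Elongation"] = float(np.sqrt(eig[1] / eig[0])) if eig[0] > 0 and eig[1] > 0 else None
        out["Flatness"] = float(np.sqrt(eig[2] / eig[0])) if eig[0] > 0 and eig[2] > 0 else None
    else:
        for name in ("MajorAxisLength", "MinorAxisLength", "LeastAxisLength", "Elongation", "Flatness"):
            out[name] = None

    slice_counts = m.sum(axis=(1, 2))
    best = int(np.argmax(slice_counts))
    pixel_area = sp[1] * sp[2]
    out["LargestSliceArea"] = float(slice_counts[best] * pixel_area)
    perim = _slice_perimeter(m[best], sp[1], sp[2])
    out["LargestSlicePerimeter"] = perim
    out["PerimeterToAreaRatio"] = (
        perim / out["LargestSliceArea"] if out["LargestSliceArea"] > 0 else None
    )
    return out
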