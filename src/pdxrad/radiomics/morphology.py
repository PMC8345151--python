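"""Shape (morphological) features of a 3-D segmented region.

All features are functions of the mask geometry alone, so they are
identical across contrasts of the same subject.  Surface quantities come
from a marching-cubes mesh of the (zero-padded) mask; axis lengths from the
principal components of the voxel-centre coordinates.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist
from skimage import measure

from ..types import BinaryMask3D

__all__ = ["morphological_features", "MORPH_FEATURES", "MORPH_CANDIDATE_ONLY"]

MORPH_FEATURES = (
    "volume_voxel",
    "volume_mesh",
    "surface_area",
    "surface_to_volume_ratio",
    "sphericity",
    "max_diameter_3d",
    "major_axis_length",
    "minor_axis_length",
    "least_axis_length",
    "elongation",
    "flatness",
    "com_shift",
)
MORPH_CANDIDATE_ONLY = (
    "compactness1",
    "compactness2",
    "spherical_disproportion",
)


_PAD = 2
_ANTIALIAS_SIGMA = 0.8  # voxels; suppresses the staircase bias of binary meshes


def _mesh(mask: np.ndarray, spacing: tuple[float, float, float]):
    # pad so masks touching the volume border still yield a closed surface;
    # mesh the anti-aliased indicator so surface area is not inflated by
    # voxelization staircase artifacts
    padded = np.pad(mask.astype(np.float64), _PAD)
    smoothed = ndimage.gaussian_filter(padded, _ANTIALIAS_SIGMA)
    if smoothed.max() <= 0.5:  # tiny masks dilute below the iso level
        smoothed = padded
    verts, faces, _, _ = measure.marching_cubes(smoothed, level=0.5, spacing=spacing)
    return verts, faces


def _mesh_volume(verts: np.ndarray, faces: np.ndarray) -> float:
    v0, v1, v2 = verts[faces[:, 0]], verts[faces[:, 1]], verts[faces[:, 2]]
    return float(abs(np.einsum("ij,ij->i", v0, np.cross(v1, v2)).sum()) / 6.0)


def _max_diameter(coords: np.ndarray) -> float:
    if coords.shape[0] == 1:
        return 0.0
    try:
        hull = ConvexHull(coords)
        pts = coords[hull.vertices]
    except QhullError:  # degenerate (coplanar/collinear) regions
        pts = np.unique(coords, axis=0)
    if pts.shape[0] > 2000:  # pathological flat masks; subsample deterministically
        pts = pts[:: pts.shape[0] // 2000 + 1]
    return float(pdist(pts).max())


def morphological_features(
    mask: BinaryMask3D, include_candidates: bool = True
) -> dict[str, float]:
    """Compute the 12 default shape features (plus 3 candidates).

    Candidates (Compactness 1/2, Spherical Disproportion) are monotone
    transforms of sphericity and are dropped from the default bank.
    """
    m = mask.voxels
    n = int(m.sum())
    if n == 0:
        raise ValueError("empty mask")
    spacing = mask.voxel_spacing
    voxvol = float(np.prod(spacing))

    feats: dict[str, float] = {}
    feats["volume_voxel"] = n * voxvol

    verts, faces = _mesh(m, spacing)
    vol_mesh = _mesh_volume(verts, faces)
    area = float(measure.mesh_surface_area(verts, faces))
    feats["volume_mesh"] = vol_mesh
    feats["surface_area"] = area
    feats["surface_to_volume_ratio"] = area / vol_mesh
    feats["sphericity"] = (36.0 * np.pi * vol_mesh**2) ** (1.0 / 3.0) / area

    coords = (np.argwhere(m) + 0.5) * np.asarray(spacing)
    feats["max_diameter_3d"] = _max_diameter(coords)

    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered / n  # population covariance
    eigvals = np.sort(np.linalg.eigvalsh(cov))[::-1]
    eigvals = np.maximum(eigvals, 0.0)
    feats["major_axis_length"] = 4.0 * np.sqrt(eigvals[0])
    feats["minor_axis_length"] = 4.0 * np.sqrt(eigvals[1])
    feats["least_axis_length"] = 4.0 * np.sqrt(eigvals[2])
    if eigvals[0] > 0:
        feats["elongation"] = float(np.sqrt(eigvals[1] / eigvals[0]))
        feats["flatness"] = float(np.sqrt(eigvals[2] / eigvals[0]))
    else:  # single voxel or degenerate
        feats["elongation"] = np.nan
        feats["flatness"] = np.nan

    # geometric centre-of-mass shift: voxel centroid vs surface-mesh centroid
    mesh_centroid = verts.mean(axis=0) - _PAD * np.asarray(spacing)  # undo padding
    # marching_cubes vertex coords are offset by half a voxel relative to centres
    feats["com_shift"] = float(
        np.linalg.norm(coords.mean(axis=0) - (mesh_centroid + 0.5 * np.asarray(spacing)))
    )

    if include_candidates:
        feats["compactness1"] = vol_mesh / (np.sqrt(np.pi) * area ** 1.5)
        feats["compactness2"] = 36.0 * np.pi * vol_mesh**2 / area**3
        feats["spherical_disproportion"] = area / (36.0 * np.pi * vol_mesh**2) ** (1.0 / 3.0)
    return feats
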