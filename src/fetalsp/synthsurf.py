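"""Synthetic surface-pair fixtures and label voxelization.

Provides geometrically controlled stand-ins for real subplate surface
reconstructions: the outer surface is an icosphere with an optional
spherical-harmonic radial perturbation, the inner surface is an inward
offset along vertex normals by a prescribed thickness field, and vertex
region labels are assigned by angular sectors (17 per hemisphere,
mirror-symmetric about the sagittal plane x = 0). Because every quantity
(thickness, area, shell volume, undulation amplitude) is known in closed
form, these fixtures serve as analytic oracles for the morphometry stage.
"""

from __future__ import annotations

import numpy as np
import trimesh as _trimesh
from scipy.spatial import cKDTree
from scipy.special import sph_harm_y

from .mesh import LabelVolume, SurfacePair, TriangleMesh
from .regions import REGIONS_17

__all__ = ["generate_surface_pair", "sector_labels", "voxelize_labels",
           "label_map_17"]

#: colatitude bands x azimuthal sectors per band summing to 17
_BANDS = (4, 5, 5, 3)


def label_map_17() -> dict[int, str]:
    """Labels 1..17 = left regions, 18..34 = the mirrored right regions."""
    out = {}
    for i, name in enumerate(REGIONS_17):
        out[i + 1] = f"L_{name}"
        out[i + 18] = f"R_{name}"
    return out


def sector_labels(vertices: np.ndarray) -> np.ndarray:
    """Mirror-symmetric angular-sector labels (1..34) for points on a
    star-shaped surface centered at the origin.

    Hemisphere from the sign of x (x < 0 -> left); within a hemisphere the
    sector depends only on (|x|, y, z), so the scheme is exactly symmetric
    under reflection through the sagittal plane.
    """
    v = np.asarray(vertices, dtype=float)
    r = np.linalg.norm(v, axis=1)
    left = v[:, 0] < 0
    ax = np.abs(v[:, 0])
    costheta = np.clip(v[:, 2] / np.maximum(r, 1e-300), -1.0, 1.0)
    theta = np.arccos(costheta)                       # colatitude in [0, pi]
    phi = np.arctan2(v[:, 1], ax)                     # azimuth in (-pi, pi]

    edges = np.cumsum((0,) + _BANDS)
    band = np.minimum((theta / np.pi * len(_BANDS)).astype(int), len(_BANDS) - 1)
    region = np.empty(len(v), dtype=np.int64)
    for b, nsec in enumerate(_BANDS):
        m = band == b
        # phi spans (-pi/2, pi/2]: one hemisphere is a half-shell
        sec = np.minimum(((phi[m] + np.pi / 2) / np.pi * nsec).astype(int),
                         nsec - 1)
        sec = np.maximum(sec, 0)
        region[m] = edges[b] + sec + 1                # 1..17
    return np.where(left, region, region + 17)


def _harmonic_pattern(vertices: np.ndarray, degree: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Random real combination of degree-l spherical harmonics, peak |.| = 1."""
    v = np.asarray(vertices, dtype=float)
    r = np.linalg.norm(v, axis=1)
    theta = np.arccos(np.clip(v[:, 2] / r, -1.0, 1.0))
    phi = np.arctan2(v[:, 1], v[:, 0])
    pattern = np.zeros(len(v))
    for m in range(0, degree + 1):
        w = rng.normal()
        pattern += w * np.real(sph_harm_y(degree, m, theta, phi))
    peak = np.max(np.abs(pattern))
    if peak == 0:
        raise ValueError("degenerate harmonic pattern")
    return pattern / peak


def generate_surface_pair(radius: float = 30.0, amplitude: float = 0.0,
                          harmonic_degree: int = 4,
                          thickness_field=2.0,
                          subdivisions: int = 4,
                          seed: int = 0) -> SurfacePair:
    """Build a corresponded outer/inner surface pair.

    outer = icosphere radially perturbed by ``amplitude`` times a unit-peak
    spherical-harmonic pattern of the given degree; inner = outer vertices
    moved inward along outer vertex normals by ``thickness_field`` (scalar
    or per-vertex, mm). Both meshes share the face list; labels are angular
    sectors.

    Raises if the requested thickness makes the inner surface fold over
    (local self-intersection) or leave the outer surface.
    """
    if amplitude < 0 or radius <= amplitude:
        raise ValueError("need radius > amplitude >= 0")
    base = _trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    unit = np.asarray(base.vertices)
    unit = unit / np.linalg.norm(unit, axis=1, keepdims=True)
    faces = np.asarray(base.faces)

    if amplitude > 0:
        rng = np.random.default_rng(seed)
        pattern = _harmonic_pattern(unit, harmonic_degree, rng)
        radial = radius + amplitude * pattern
    else:
        radial = np.full(len(unit), float(radius))
    outer_v = unit * radial[:, None]

    thickness = np.broadcast_to(np.asarray(thickness_field, dtype=float),
                                (len(unit),)).copy()
    if np.any(thickness <= 0) or np.any(thickness >= radius / 2.0):
        raise ValueError("thickness_field must be positive and < radius/2")

    labels = sector_labels(outer_v)
    outer = TriangleMesh(outer_v, faces, labels)
    normals = outer.vertex_normals
    inner_v = outer_v - thickness[:, None] * normals

    inner = TriangleMesh(inner_v, faces, labels.copy())
    # reject locally folded inner surfaces: a face whose normal flipped
    # relative to its outer counterpart indicates self-intersection
    outer_fn = np.asarray(outer.to_trimesh().face_normals)
    inner_fn = np.asarray(inner.to_trimesh().face_normals)
    flipped = np.sum(outer_fn * inner_fn, axis=1) <= 0
    if flipped.any():
        raise ValueError(
            f"inner surface self-intersects ({int(flipped.sum())} flipped "
            "faces); thickness too large for local curvature")
    return SurfacePair(outer=outer, inner=inner)


def voxelize_labels(pair: SurfacePair, voxel_size: float = 0.5,
                    origin=None, chunk: int = 1_000_000) -> LabelVolume:
    """Label the voxels whose centers lie between the inner and outer surface.

    A voxel center p is inside the shell when its signed pseudonormal
    distance to the outer surface is <= 0 (inside) and to the inner surface
    is >= 0 (outside); each such voxel receives the region label of its
    nearest outer vertex. Signed distances use the nearest corresponded
    vertex and its normal, which is accurate for the dense, smooth,
    star-shaped fixtures this module generates.
    """
    if voxel_size <= 0:
        raise ValueError("voxel_size must be positive")
    outer, inner = pair.outer, pair.inner
    thickness = np.linalg.norm(outer.vertices - inner.vertices, axis=1)
    r_out = np.linalg.norm(outer.vertices, axis=1)
    r_in = np.linalg.norm(inner.vertices, axis=1)
    if np.mean(r_in) > np.mean(r_out):
        raise ValueError("degenerate pair: inner surface outside outer")
    if np.all(thickness <= 1e-12):
        # zero-thickness shell encloses no voxel centers
        return LabelVolume(np.zeros((1, 1, 1), dtype=np.int64), voxel_size,
                           label_map_17(), origin=outer.vertices.min(axis=0))

    # origin override supports convergence studies over shifted grids
    lo = (np.asarray(origin, dtype=float) if origin is not None
          else outer.vertices.min(axis=0) - voxel_size)
    hi = outer.vertices.max(axis=0) + voxel_size
    if np.any(lo > outer.vertices.min(axis=0) - 0.5 * voxel_size):
        raise ValueError("origin must lie below the outer surface bbox")
    shape = np.ceil((hi - lo) / voxel_size).astype(int)
    grid = np.zeros(shape, dtype=np.int64)

    normals = outer.vertex_normals   # shared by correspondence
    tree_out = cKDTree(outer.vertices)
    tree_in = cKDTree(inner.vertices)
    labels = outer.vertex_labels

    ii, jj, kk = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    idx = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
    flat = grid.reshape(-1)
    for start in range(0, idx.shape[0], chunk):
        sl = idx[start:start + chunk]
        p = lo + (sl + 0.5) * voxel_size
        _, near_out = tree_out.query(p, workers=-1)
        s_out = np.einsum("ij,ij->i", p - outer.vertices[near_out],
                          normals[near_out])
        _, near_in = tree_in.query(p, workers=-1)
        s_in = np.einsum("ij,ij->i", p - inner.vertices[near_in],
                         normals[near_in])
        inside = (s_out <= 0.0) & (s_in >= 0.0)
        flat_index = start + np.flatnonzero(inside)
        flat[flat_index] = labels[near_out[inside]]
    return LabelVolume(grid, voxel_size, label_map_17(), origin=lo)
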