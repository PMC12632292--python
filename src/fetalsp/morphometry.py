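"""Geometric subplate measures from surface pairs and label volumes.

Thickness is the Euclidean distance between corresponded inner and outer
vertices; surface area sums triangle areas (per region by majority vertex
label); regional volume counts labeled voxels times voxel volume; depth is
the signed normal displacement from an inflated reference surface, rescaled
so each subject's minimum is zero. Surface quality is summarized by a
smoothness error (local mean-curvature roughness) and a boundary distance
error (mean vertex distance to the nearest label-boundary voxel).
"""

from __future__ import annotations

import numpy as np
import trimesh as _trimesh
from scipy import ndimage, sparse
from trimesh.smoothing import laplacian_calculation

from .mesh import LabelVolume, SurfacePair, TriangleMesh

__all__ = [
    "taubin_smooth",
    "vertex_thickness",
    "inflate_surface",
    "sp_depth",
    "surface_area",
    "region_volume",
    "regional_median",
    "surface_qc",
    "mean_curvature",
]


def _uniform_laplacian(mesh: TriangleMesh) -> sparse.csr_matrix:
    """Row-stochastic vertex-adjacency averaging operator."""
    return laplacian_calculation(mesh.to_trimesh(), equal_weight=True).tocsr()


def taubin_smooth(mesh: TriangleMesh, lam: float = 0.5, mu: float = -0.53,
                  iterations: int = 10) -> TriangleMesh:
    """Shrink-compensated two-step Laplacian (Taubin) smoothing.

    Each iteration applies an inflating-free pair of uniform-Laplacian
    steps: first with factor ``lam`` (shrink), then with ``mu`` (negative;
    dilate). Requires 0 < lam < -mu < 1. Topology is unchanged; on a closed
    mesh the enclosed volume changes by well under 1% at the defaults.
    """
    if not (0.0 < lam < -mu < 1.0):
        raise ValueError("need 0 < lam < -mu < 1 for shrink compensation")
    if not mesh.is_closed:
        raise ValueError("taubin_smooth requires a closed, manifold mesh")
    L = _uniform_laplacian(mesh)
    v = mesh.vertices.copy()
    for _ in range(int(iterations)):
        v = v + lam * (L @ v - v)
        v = v + mu * (L @ v - v)
    return mesh.with_vertices(v)


def vertex_thickness(pair: SurfacePair) -> np.ndarray:
    """Per-vertex SP thickness: |outer_i - inner_i| in mm (nonnegative)."""
    return np.linalg.norm(pair.outer.vertices - pair.inner.vertices, axis=1)


def inflate_surface(mesh: TriangleMesh, iterations: int = 300,
                    step: float = 0.9) -> TriangleMesh:
    """Area-preserving inflation: iterative Laplacian smoothing with a
    per-iteration rescale about the centroid restoring total surface area.

    Smooths away undulations (sulcal geometry) while keeping size, giving
    the smooth reference surface that depth is measured against. A sphere
    is a fixed point up to tolerance.
    """
    if not mesh.is_closed:
        raise ValueError("inflate_surface requires a closed mesh")
    target = mesh.face_areas().sum()
    v = mesh.vertices.copy()
    work = mesh
    for _ in range(int(iterations)):
        # mass-normalized cotangent Laplacian: displacement is exactly the
        # mean-curvature normal (-2 H n), so a sphere shrinks uniformly and
        # the area rescale restores it (true fixed point); the time step is
        # bounded by the stiffest vertex for explicit stability
        W, area3 = _cotangent_weights(work)
        diag = np.asarray(W.sum(axis=1)).ravel()
        dt = step / np.max(diag / np.maximum(area3, 1e-300))
        v = v + dt * (W @ v - diag[:, None] * v) / area3[:, None]
        work = mesh.with_vertices(v)
        area = work.face_areas().sum()
        centroid = v.mean(axis=0)
        v = centroid + (v - centroid) * np.sqrt(target / area)
        work = mesh.with_vertices(v)
    return work


def sp_depth(mesh: TriangleMesh, inflated: TriangleMesh) -> np.ndarray:
    """Sulcal-style depth: signed normal displacement from the inflated
    surface to the original vertices, rescaled so the minimum over all
    vertices (both hemispheres) is exactly zero.
    """
    if mesh.vertices.shape != inflated.vertices.shape or \
            not np.array_equal(mesh.faces, inflated.faces):
        raise ValueError("mesh and inflated surface must correspond")
    normals = inflated.vertex_normals
    disp = np.einsum("ij,ij->i", mesh.vertices - inflated.vertices, normals)
    return disp - disp.min()


def _face_regions(mesh: TriangleMesh) -> np.ndarray:
    """Triangle region = majority vertex label; ties -> lowest region id."""
    fl = mesh.vertex_labels[mesh.faces]          # (M, 3)
    fl = np.sort(fl, axis=1)
    out = fl[:, 0].copy()                        # lowest id wins 1-1-1 ties
    pair_hi = fl[:, 1] == fl[:, 2]               # two highest agree -> majority
    out[pair_hi] = fl[pair_hi, 1]
    pair_lo = fl[:, 0] == fl[:, 1]
    out[pair_lo] = fl[pair_lo, 0]
    return out


def surface_area(mesh: TriangleMesh, by_region: bool = False):
    """Total triangle area (mm^2), optionally also per region.

    Per-region sums partition the total exactly (each triangle is assigned
    to exactly one region by majority vertex label).
    """
    areas = mesh.face_areas()
    total = float(areas.sum())
    if not by_region:
        return total
    if mesh.vertex_labels is None:
        raise ValueError("mesh has no vertex labels")
    regions = _face_regions(mesh)
    per = {int(r): float(areas[regions == r].sum()) for r in np.unique(regions)}
    return total, per


def region_volume(volume: LabelVolume) -> tuple[float, dict[int, float]]:
    """(whole-brain total, per-region volume) in mm^3: voxel counts times
    voxel volume."""
    vv = volume.voxel_size ** 3
    labels, counts = np.unique(volume.grid, return_counts=True)
    per = {int(l): float(c * vv) for l, c in zip(labels, counts) if l != 0}
    return float(sum(per.values())), per


def regional_median(values: np.ndarray, labels: np.ndarray,
                    exclude: set[int] = frozenset()) -> dict[int, float]:
    """Median of a per-vertex field within each region label.

    Excluded labels are dropped; a region with no vertices is reported as
    NaN (missing), never as zero.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.shape[0] != labels.shape[0]:
        raise ValueError("values and labels must have equal length")
    out: dict[int, float] = {}
    for lab in np.unique(labels):
        if int(lab) in exclude or lab == 0:
            continue
        sel = values[labels == lab]
        out[int(lab)] = float(np.median(sel)) if sel.size else float("nan")
    return out


def _cotangent_weights(mesh: TriangleMesh):
    """Symmetric cotangent edge weights W and mixed-Voronoi vertex areas.

    Voronoi corner areas (|e|^2 cot / 8) are exact for acute triangulations;
    obtuse corners fall back to the barycentric third, keeping areas
    positive on arbitrary meshes.
    """
    v, f = mesh.vertices, mesh.faces
    n = len(v)
    face_area = mesh.face_areas()
    voronoi = np.zeros(n)
    bary = np.zeros(n)
    obtuse_face = np.zeros(len(f), dtype=bool)
    rows, cols, vals = [], [], []
    cots = []
    for k in range(3):
        i, j, o = f[:, k], f[:, (k + 1) % 3], f[:, (k + 2) % 3]
        # cotangent at the vertex opposite edge (i, j)
        a = v[i] - v[o]
        b = v[j] - v[o]
        cos = np.einsum("ij,ij->i", a, b)
        sin = np.linalg.norm(np.cross(a, b), axis=1)
        cot = 0.5 * cos / np.maximum(sin, 1e-300)
        rows.extend([i, j])
        cols.extend([j, i])
        vals.extend([cot, cot])
        cots.append(cot)
        obtuse_face |= cos < 0
        np.add.at(bary, i, face_area / 3.0)
    for k in range(3):
        i, j = f[:, k], f[:, (k + 1) % 3]
        e2 = np.einsum("ij,ij->i", v[i] - v[j], v[i] - v[j])
        contrib = np.where(obtuse_face, 0.0, e2 * cots[k] / 2.0)
        np.add.at(voronoi, i, contrib / 2.0)
        np.add.at(voronoi, j, contrib / 2.0)
    # vertices touching any obtuse face use the barycentric area instead
    area = np.where(voronoi > 0, voronoi, bary)
    touched = np.zeros(n, dtype=bool)
    np.add.at(touched, f[obtuse_face].ravel(), True)
    area[touched] = bary[touched]
    W = sparse.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n)).tocsr()
    return W, area


def mean_curvature(mesh: TriangleMesh) -> np.ndarray:
    """Signed discrete mean curvature per vertex (cotangent Laplace-Beltrami
    with barycentric vertex areas); H = 1/R on a sphere of radius R."""
    W, area3 = _cotangent_weights(mesh)
    v = mesh.vertices
    diag = np.asarray(W.sum(axis=1)).ravel()
    lap = (W @ v - diag[:, None] * v) / np.maximum(area3, 1e-300)[:, None]
    normals = mesh.vertex_normals
    # Delta v = -2 H n with outward normals on a convex surface
    return -0.5 * np.einsum("ij,ij->i", lap, normals)


def _vertex_adjacency(mesh: TriangleMesh) -> sparse.csr_matrix:
    n = len(mesh.vertices)
    f = mesh.faces
    rows = np.concatenate([f[:, 0], f[:, 1], f[:, 2], f[:, 1], f[:, 2], f[:, 0]])
    cols = np.concatenate([f[:, 1], f[:, 2], f[:, 0], f[:, 0], f[:, 1], f[:, 2]])
    A = sparse.coo_matrix((np.ones(rows.size), (rows, cols)), shape=(n, n)).tocsr()
    A.data[:] = 1.0
    return A


def surface_qc(mesh: TriangleMesh, volume: LabelVolume
               ) -> tuple[float, float]:
    """(smoothness_error, boundary_distance_error) of a surface against its
    label volume, both in the volume's world frame.

    smoothness_error: mean over vertices of |H(v) - mean H(neighbors)| with
    discrete mean curvature H. boundary_distance_error: mean Euclidean
    distance (mm) from each vertex to the nearest voxel center on the label
    boundary (labeled voxels with a background neighbor), via a distance
    transform sampled at the vertices.
    """
    H = mean_curvature(mesh)
    A = _vertex_adjacency(mesh)
    deg = np.asarray(A.sum(axis=1)).ravel()
    neigh_mean = (A @ H) / np.maximum(deg, 1.0)
    smoothness = float(np.mean(np.abs(H - neigh_mean)))

    mask = volume.grid > 0
    boundary = mask & ~ndimage.binary_erosion(mask)
    if not boundary.any():
        raise ValueError("label volume has an empty boundary mask")
    dist_vox = ndimage.distance_transform_edt(~boundary)
    coords = volume.world_to_index(mesh.vertices)
    d = ndimage.map_coordinates(dist_vox, coords.T, order=1, mode="nearest")
    boundary_err = float(np.mean(d) * volume.voxel_size)
    return smoothness, boundary_err
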