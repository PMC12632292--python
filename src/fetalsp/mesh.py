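"""Mesh and label-volume containers with GIFTI / OBJ / NIfTI round-trips.

Coordinates are world millimeters throughout. Voxel grids use the
half-voxel convention: the center of voxel (i, j, k) sits at
``origin + (index + 0.5) * voxel_size``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import trimesh as _trimesh

__all__ = ["TriangleMesh", "SurfacePair", "LabelVolume",
           "load_surface", "save_surface", "load_label_volume",
           "save_label_volume"]


@dataclass
class TriangleMesh:
    """A triangle surface: vertices (N, 3) in mm, faces (M, 3) indices,
    optional per-vertex integer region labels."""

    vertices: np.ndarray
    faces: np.ndarray
    vertex_labels: np.ndarray | None = None

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.faces.max(initial=-1) >= len(self.vertices) or self.faces.min(initial=0) < 0:
            raise ValueError("faces index out-of-range vertices")
        areas = self.face_areas()
        if np.any(areas <= 0):
            raise ValueError("mesh contains degenerate (zero-area) faces")
        if self.vertex_labels is not None:
            self.vertex_labels = np.asarray(self.vertex_labels, dtype=np.int64)
            if self.vertex_labels.shape[0] != self.vertices.shape[0]:
                raise ValueError("one label per vertex required")

    # -- geometry -----------------------------------------------------------
    def to_trimesh(self) -> _trimesh.Trimesh:
        return _trimesh.Trimesh(vertices=self.vertices, faces=self.faces,
                                process=False)

    def face_areas(self) -> np.ndarray:
        v = self.vertices
        a = v[self.faces[:, 1]] - v[self.faces[:, 0]]
        b = v[self.faces[:, 2]] - v[self.faces[:, 0]]
        return 0.5 * np.linalg.norm(np.cross(a, b), axis=1)

    @property
    def vertex_normals(self) -> np.ndarray:
        """Unit outward vertex normals (area-weighted from trimesh)."""
        return np.asarray(self.to_trimesh().vertex_normals, dtype=float)

    @property
    def is_closed(self) -> bool:
        return bool(self.to_trimesh().is_watertight)

    def with_vertices(self, vertices: np.ndarray) -> "TriangleMesh":
        return TriangleMesh(vertices, self.faces.copy(),
                            None if self.vertex_labels is None
                            else self.vertex_labels.copy())

    def copy(self) -> "TriangleMesh":
        return self.with_vertices(self.vertices.copy())


@dataclass
class SurfacePair:
    """Topology-identical outer (CP/SP) and inner (SP/IZ) surfaces.

    Vertex i of the inner mesh corresponds to vertex i of the outer mesh;
    the face lists are identical.
    """

    outer: TriangleMesh
    inner: TriangleMesh

    def __post_init__(self):
        if self.outer.vertices.shape != self.inner.vertices.shape:
            raise ValueError("outer and inner must have the same vertex count")
        if not np.array_equal(self.outer.faces, self.inner.faces):
            raise ValueError("outer and inner must share an identical face list")


@dataclass
class LabelVolume:
    """Integer region-label grid at isotropic voxel size (mm)."""

    grid: np.ndarray
    voxel_size: float
    label_map: dict[int, str] = field(default_factory=dict)
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.grid = np.asarray(self.grid)
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        self.origin = np.asarray(self.origin, dtype=float)
        present = set(np.unique(self.grid)) - {0}
        unknown = present - set(self.label_map)
        if self.label_map and unknown:
            raise ValueError(f"labels missing from label_map: {sorted(unknown)}")

    def voxel_centers_world(self, indices: np.ndarray) -> np.ndarray:
        return self.origin + (np.asarray(indices, dtype=float) + 0.5) * self.voxel_size

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Fractional voxel indices of world points (inverse of centers)."""
        return (np.asarray(points, dtype=float) - self.origin) / self.voxel_size - 0.5


# --------------------------------------------------------------------------
# I/O

def save_surface(mesh: TriangleMesh, path) -> None:
    """Write a surface as GIFTI (.gii, with labels as a shape array) or OBJ."""
    path = Path(path)
    if path.suffix == ".obj":
        mesh.to_trimesh().export(path)
        return
    darrays = [
        nib.gifti.GiftiDataArray(mesh.vertices.astype(np.float32),
                                 intent="NIFTI_INTENT_POINTSET"),
        nib.gifti.GiftiDataArray(mesh.faces.astype(np.int32),
                                 intent="NIFTI_INTENT_TRIANGLE"),
    ]
    if mesh.vertex_labels is not None:
        darrays.append(nib.gifti.GiftiDataArray(
            mesh.vertex_labels.astype(np.int32), intent="NIFTI_INTENT_LABEL"))
    nib.save(nib.gifti.GiftiImage(darrays=darrays), path)


def load_surface(path) -> TriangleMesh:
    path = Path(path)
    if path.suffix == ".obj":
        tm = _trimesh.load(path, process=False)
        return TriangleMesh(np.asarray(tm.vertices), np.asarray(tm.faces))
    img = nib.load(path)
    verts = faces = labels = None
    for da in img.darrays:
        code = da.intent
        if code == nib.nifti1.intent_codes["NIFTI_INTENT_POINTSET"]:
            verts = da.data
        elif code == nib.nifti1.intent_codes["NIFTI_INTENT_TRIANGLE"]:
            faces = da.data
        elif code == nib.nifti1.intent_codes["NIFTI_INTENT_LABEL"]:
            labels = da.data
    if verts is None or faces is None:
        raise ValueError(f"{path} lacks pointset/triangle arrays")
    return TriangleMesh(verts, faces, labels)


def save_label_volume(vol: LabelVolume, path) -> None:
    affine = np.diag([vol.voxel_size] * 3 + [1.0])
    affine[:3, 3] = vol.origin + 0.5 * vol.voxel_size  # voxel-center origin
    img = nib.Nifti1Image(vol.grid.astype(np.int16), affine)
    img.header.set_zooms((vol.voxel_size,) * 3)
    nib.save(img, path)


def load_label_volume(path, label_map: dict[int, str] | None = None) -> LabelVolume:
    img = nib.load(path)
    zooms = img.header.get_zooms()[:3]
    if not np.allclose(zooms, zooms[0]):
        raise ValueError("anisotropic label volumes are not supported")
    origin = np.asarray(img.affine[:3, 3]) - 0.5 * zooms[0]
    return LabelVolume(np.asarray(img.dataobj).astype(np.int64), float(zooms[0]),
                       label_map or {}, origin)
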