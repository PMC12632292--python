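"""Geometric measures: smoothing, thickness, depth, areas, volumes, QC."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from fetalsp.mesh import SurfacePair, TriangleMesh
from fetalsp.morphometry import (inflate_surface, mean_curvature,
                                 region_volume, regional_median, sp_depth,
                                 surface_area, surface_qc, taubin_smooth,
                                 vertex_thickness)
from fetalsp.mesh import LabelVolume
from fetalsp.synthsurf import generate_surface_pair, voxelize_labels


# ---------------------------------------------------------------- smoothing

def test_taubin_zero_iterations_is_identity(sphere_pair):
    out = taubin_smooth(sphere_pair.outer, iterations=0)
    np.testing.assert_array_equal(out.vertices, sphere_pair.outer.vertices)


def test_taubin_preserves_sphere_radius_and_volume(sphere_pair):
    out = taubin_smooth(sphere_pair.outer)
    r = np.linalg.norm(out.vertices, axis=1)
    assert np.abs(r - 25.0).max() < 0.1
    v0 = sphere_pair.outer.to_trimesh().volume
    v1 = out.to_trimesh().volume
    assert abs(v1 - v0) / v0 < 0.01


def test_taubin_damps_high_frequency_noise_monotonically(sphere_pair, rng):
    base = sphere_pair.outer
    unit = base.vertices / np.linalg.norm(base.vertices, axis=1, keepdims=True)
    noisy = base.with_vertices(base.vertices
                               + 0.3 * rng.normal(size=(len(unit), 1)) * unit)
    amps = []
    mesh = noisy
    for _ in range(4):
        r = np.linalg.norm(mesh.vertices, axis=1)
        amps.append(np.std(r - 25.0))
        mesh = taubin_smooth(mesh, iterations=3)
    assert amps[0] > amps[1] > amps[2] > amps[3]


def test_taubin_invalid_factors_rejected(sphere_pair):
    with pytest.raises(ValueError):
        taubin_smooth(sphere_pair.outer, lam=0.6, mu=-0.5)


def test_taubin_rejects_open_mesh(sphere_pair):
    open_mesh = TriangleMesh(sphere_pair.outer.vertices,
                             sphere_pair.outer.faces[:-10])
    with pytest.raises(ValueError):
        taubin_smooth(open_mesh)


# ---------------------------------------------------------------- thickness

def test_identical_meshes_have_zero_thickness(sphere_pair):
    pair = SurfacePair(sphere_pair.outer, sphere_pair.outer.copy())
    assert vertex_thickness(pair).max() == 0.0


def test_constructed_normal_offset_recovered_on_perturbed_sphere():
    pair = generate_surface_pair(radius=30.0, amplitude=2.0, harmonic_degree=4,
                                 thickness_field=3.0, subdivisions=4, seed=2)
    np.testing.assert_allclose(vertex_thickness(pair), 3.0, atol=1e-9)


def test_thickness_invariant_under_rigid_motion(perturbed_pair):
    R = Rotation.from_euler("xyz", [0.3, -1.1, 2.0]).as_matrix()
    t = np.array([5.0, -3.0, 11.0])
    moved = SurfacePair(
        perturbed_pair.outer.with_vertices(perturbed_pair.outer.vertices @ R.T + t),
        perturbed_pair.inner.with_vertices(perturbed_pair.inner.vertices @ R.T + t))
    np.testing.assert_allclose(vertex_thickness(moved),
                               vertex_thickness(perturbed_pair), atol=1e-9)


def test_mismatched_topology_rejected(sphere_pair):
    coarse = generate_surface_pair(radius=25.0, amplitude=0.0,
                                   thickness_field=2.0, subdivisions=3)
    with pytest.raises(ValueError):
        SurfacePair(sphere_pair.outer, coarse.inner)


# ---------------------------------------------------------------- inflation

def test_sphere_is_fixed_point_of_inflation(sphere_pair):
    out = inflate_surface(sphere_pair.outer, iterations=100)
    r = np.linalg.norm(out.vertices, axis=1)
    assert np.abs(r - 25.0).max() < 0.002 * 25.0


def test_inflation_removes_undulations_and_preserves_area(perturbed_pair):
    outer = perturbed_pair.outer
    infl = inflate_surface(outer)
    r = np.linalg.norm(infl.vertices, axis=1)
    assert np.ptp(r) / 2.0 < 0.05 * 3.0        # residual amplitude < 5% of input
    a0, a1 = surface_area(outer), surface_area(infl)
    assert a1 == pytest.approx(a0, rel=0.01)


def test_inflation_rejects_open_mesh(sphere_pair):
    open_mesh = TriangleMesh(sphere_pair.outer.vertices,
                             sphere_pair.outer.faces[:-10])
    with pytest.raises(ValueError):
        inflate_surface(open_mesh)


# ---------------------------------------------------------------- depth

def test_depth_of_sphere_against_itself_is_zero(sphere_pair):
    d = sp_depth(sphere_pair.outer, sphere_pair.outer.copy())
    np.testing.assert_allclose(d, 0.0, atol=1e-12)


def test_depth_minimum_is_exactly_zero(perturbed_pair):
    d = sp_depth(perturbed_pair.outer, inflate_surface(perturbed_pair.outer))
    assert d.min() == 0.0
    assert d.max() > 0.0


def test_single_harmonic_depth_range_matches_construction(perturbed_pair):
    # amplitude-3 harmonic perturbation spans peaks to troughs ~ 2A
    d = sp_depth(perturbed_pair.outer, inflate_surface(perturbed_pair.outer))
    assert np.ptp(d) == pytest.approx(6.0, rel=0.2)


def test_depth_correspondence_mismatch_rejected(sphere_pair):
    coarse = generate_surface_pair(radius=25.0, amplitude=0.0,
                                   thickness_field=2.0, subdivisions=3)
    with pytest.raises(ValueError):
        sp_depth(sphere_pair.outer, coarse.outer)


# ---------------------------------------------------------------- area

def test_single_right_triangle_area():
    mesh = TriangleMesh(np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0.0]]),
                        np.array([[0, 1, 2]]))
    assert surface_area(mesh) == pytest.approx(0.5)


def test_area_scales_quadratically(perturbed_pair):
    m = perturbed_pair.outer
    doubled = m.with_vertices(2.0 * m.vertices)
    assert surface_area(doubled) == pytest.approx(4.0 * surface_area(m))


def test_per_region_areas_partition_total(sphere_pair):
    total, per = surface_area(sphere_pair.outer, by_region=True)
    assert sum(per.values()) == pytest.approx(total, rel=1e-12)


def test_face_region_majority_and_tie_rules():
    verts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0],
                      [1, 1, 0.0]])
    faces = np.array([[0, 1, 2], [1, 3, 2]])
    mesh = TriangleMesh(verts, faces, vertex_labels=np.array([2, 2, 5, 7]))
    _, per = surface_area(mesh, by_region=True)
    # face 0: labels (2,2,5) -> majority 2; face 1: (2,7,5) tie -> lowest id 2
    assert set(per) == {2}


# ---------------------------------------------------------------- volume

def test_region_volume_counts_times_voxel_volume():
    grid = np.zeros((5, 5, 5), dtype=int)
    grid.flat[:10] = 3                      # 10 voxels at 0.5 mm -> 1.25 mm^3
    total, per = region_volume(LabelVolume(grid, voxel_size=0.5))
    assert per[3] == pytest.approx(1.25)
    assert total == pytest.approx(1.25)


def test_empty_grid_has_zero_volume():
    total, per = region_volume(LabelVolume(np.zeros((3, 3, 3), int), 0.5))
    assert total == 0.0 and per == {}


# ---------------------------------------------------------------- medians

def test_regional_median_constant_field():
    med = regional_median(np.full(30, 4.2), np.repeat([1, 2, 3], 10))
    assert med == {1: 4.2, 2: 4.2, 3: 4.2}


def test_regional_median_is_outlier_robust():
    med = regional_median(np.array([1.0, 2.0, 100.0]), np.array([4, 4, 4]))
    assert med[4] == 2.0


def test_regional_median_matches_brute_force_sort(rng):
    values = rng.normal(size=2000)
    labels = rng.integers(1, 18, size=2000)
    med = regional_median(values, labels)
    for lab in np.unique(labels):
        sel = np.sort(values[labels == lab])
        n = len(sel)
        brute = sel[n // 2] if n % 2 else 0.5 * (sel[n // 2 - 1] + sel[n // 2])
        assert med[int(lab)] == pytest.approx(brute)


def test_excluded_labels_are_dropped():
    med = regional_median(np.arange(20.0), np.repeat([1, 2], 10), exclude={2})
    assert set(med) == {1}


# ---------------------------------------------------------------- QC

def test_sphere_mean_curvature_is_one_over_radius(sphere_pair):
    H = mean_curvature(sphere_pair.outer)
    np.testing.assert_allclose(H, 1.0 / 25.0, rtol=0.05)


def test_sphere_smoothness_error_is_tiny(sphere_pair):
    vol = voxelize_labels(sphere_pair, voxel_size=1.0)
    smooth, _ = surface_qc(sphere_pair.outer, vol)
    assert smooth < 1e-3


def test_boundary_distance_error_sees_displacement(sphere_pair):
    vol = voxelize_labels(sphere_pair, voxel_size=1.0)
    _, bd0 = surface_qc(sphere_pair.outer, vol)
    moved = sphere_pair.outer.with_vertices(
        sphere_pair.outer.vertices * (26.0 / 25.0))  # 1 mm radial offset
    _, bd1 = surface_qc(moved, vol)
    assert bd1 == pytest.approx(bd0 + 1.0, abs=0.35)


def test_empty_boundary_mask_rejected(sphere_pair):
    empty = LabelVolume(np.zeros((4, 4, 4), int), 1.0)
    with pytest.raises(ValueError):
        surface_qc(sphere_pair.outer, empty)
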