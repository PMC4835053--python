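"""Mesh construction, point location and surface queries."""

import numpy as np
import pytest

from ablaquant.errors import MeshError
from ablaquant.hexmesh import (build_mesh, label_surface_points,
                               shape_functions, write_vtk)
from ablaquant.imaging_io import LabelMap


def test_empty_labelmap_raises():
    with pytest.raises(MeshError):
        build_mesh(LabelMap(np.zeros((8, 8, 8), dtype=np.int32)), 1.0, 1.0)


def test_min_size_below_voxel_resolution_rejected(cube_labels):
    with pytest.raises(MeshError):
        build_mesh(cube_labels, 0.2, 1.0)


def test_cube_element_and_node_counts(cube_labels):
    # 10 mm cube at 1 mm elements, no margin: 10^3 elements, 11^3 nodes
    mesh = build_mesh(cube_labels, 1.0, 1.0, margin=0.0)
    assert mesh.n_elements == 1000
    assert mesh.n_nodes == 1331
    assert np.all(mesh.element_label == 1)
    # element volumes sum to the bounding-box volume exactly
    assert mesh.element_volumes().sum() == pytest.approx(1000.0)


def test_locate_element_center_and_corners(cube_labels):
    mesh = build_mesh(cube_labels, 1.0, 1.0, margin=0.0)
    eid, local = mesh.locate_element(mesh.element_centers()[37])
    assert eid == 37
    assert np.allclose(local, 0.0, atol=1e-12)
    corner = mesh.node_coords[mesh.elements[0, 6]]  # (+,+,+) corner of elem 0
    _, local = mesh.locate_element(corner)
    assert np.allclose(np.abs(local), 1.0, atol=1e-9)


def test_locate_elements_forward_map(cube_labels, rng):
    mesh = build_mesh(cube_labels, 1.0, 1.0, margin=0.0)
    pts = rng.uniform(0.6, 10.4, size=(1000, 3))
    eids, local = mesh.locate_elements(pts)
    assert (eids >= 0).all()
    rec = np.einsum("ma,mad->md", shape_functions(local),
                    mesh.node_coords[mesh.elements[eids]])
    assert np.abs(rec - pts).max() < 1e-9


def test_outside_point_returns_outside_marker(cube_labels):
    mesh = build_mesh(cube_labels, 1.0, 1.0, margin=0.0)
    eid, _ = mesh.locate_element((99.0, 0.0, 0.0))
    assert eid is None


def test_mesh_covers_all_labeled_voxels(tiny_phantom):
    _, labels = tiny_phantom
    mesh = build_mesh(labels, 2.0, 2.0, margin=4.0)
    idx = np.array(np.nonzero(labels.labels > 0)).T
    pts = labels.voxel_to_world(idx)
    eids, _ = mesh.locate_elements(pts)
    assert (eids >= 0).all()


def test_surface_node_count_matches_structured_formula(cube_labels):
    mesh = build_mesh(cube_labels, 1.0, 1.0, margin=0.0)
    nodes, normals = mesh.surface_nodes(1)
    n = 10
    assert len(nodes) == (n + 1) ** 3 - (n - 1) ** 3
    assert np.allclose(np.linalg.norm(normals, axis=1), 1.0)


def test_surface_normals_point_radially_outward():
    # sphere of radius 10 mm in a 28^3 grid
    g = np.arange(28)
    x, y, z = np.meshgrid(g, g, g, indexing="ij")
    mask = (x - 13.5) ** 2 + (y - 13.5) ** 2 + (z - 13.5) ** 2 <= 100.0
    labels = LabelMap(mask.astype(np.int32))
    mesh = build_mesh(labels, 1.0, 1.0, margin=2.0)
    nodes, normals = mesh.surface_nodes(1)
    radial = mesh.node_coords[nodes] - np.array([13.5, 13.5, 13.5])
    radial /= np.linalg.norm(radial, axis=1, keepdims=True)
    mean_cos = np.mean(np.sum(normals * radial, axis=1))
    assert mean_cos > 0.95


def test_interior_nodes_never_on_surface(cube_labels):
    mesh = build_mesh(cube_labels, 1.0, 1.0, margin=0.0)
    nodes, _ = mesh.surface_nodes(1)
    interior = mesh.node_coords[nodes]
    lo, hi = mesh.bounds()
    on_boundary = np.any(
        np.isclose(interior, lo) | np.isclose(interior, hi), axis=1)
    assert on_boundary.all()  # cube organ boundary == mesh boundary here


def test_missing_label_raises(cube_labels):
    mesh = build_mesh(cube_labels, 1.0, 1.0, margin=0.0)
    with pytest.raises(KeyError):
        mesh.surface_nodes(5)


class TestAdaptive:
    @pytest.fixture(scope="class")
    def sphere_labels(self):
        g = np.arange(24)
        x, y, z = np.meshgrid(g, g, g, indexing="ij")
        mask = (x - 11.5) ** 2 + (y - 11.5) ** 2 + (z - 11.5) ** 2 <= 64.0
        return LabelMap(mask.astype(np.int32))

    @pytest.fixture(scope="class")
    def adaptive_mesh(self, sphere_labels):
        return build_mesh(sphere_labels, min_size=1.0, max_size=4.0,
                          adaptive=True, margin=4.0)

    def test_surface_elements_smaller_than_interior(self, adaptive_mesh,
                                                    sphere_labels):
        mesh = adaptive_mesh
        centers = mesh.element_centers()
        r = np.linalg.norm(centers - np.array([11.5, 11.5, 11.5]), axis=1)
        near_surface = np.abs(r - 8.0) < 2.0
        interior = r < 5.0
        assert near_surface.any() and interior.any()
        assert (mesh.element_size[near_surface, 0].mean()
                < mesh.element_size[interior, 0].mean())

    def test_hanging_constraints_are_partitions(self, adaptive_mesh):
        assert adaptive_mesh.hanging, "octree mesh must record hanging nodes"
        for c in adaptive_mesh.hanging:
            assert c.weights.sum() == pytest.approx(1.0, abs=1e-9)
            # slave position reproduced by master interpolation
            p = (c.weights[:, None]
                 * adaptive_mesh.node_coords[c.masters]).sum(axis=0)
            assert np.allclose(p, adaptive_mesh.node_coords[c.slave],
                               atol=1e-6)

    def test_positive_volumes_and_coverage(self, adaptive_mesh, sphere_labels):
        assert (adaptive_mesh.element_volumes() > 0).all()
        idx = np.array(np.nonzero(sphere_labels.labels > 0)).T
        pts = sphere_labels.voxel_to_world(idx)
        eids, _ = adaptive_mesh.locate_elements(pts)
        assert (eids >= 0).all()


def test_label_surface_points_lie_on_cube_boundary(cube_labels):
    pts = label_surface_points(cube_labels, 1)
    assert len(pts) > 100
    # every point within a voxel of the 10 mm cube's surface shell
    inside = np.clip(pts, 0.5, 10.5)
    face_dist = np.min(np.minimum(np.abs(pts - 0.5), np.abs(pts - 10.5)),
                       axis=1)
    assert np.allclose(pts, inside, atol=1e-6)
    assert face_dist.max() < 1.0


def test_vtk_export_is_readable_text(tmp_path, cube_labels):
    mesh = build_mesh(cube_labels, 2.0, 2.0, margin=0.0)
    path = tmp_path / "mesh.vtk"
    write_vtk(mesh, path)
    text = path.read_text()
    assert "UNSTRUCTURED_GRID" in text
    assert f"POINTS {mesh.n_nodes}" in text
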