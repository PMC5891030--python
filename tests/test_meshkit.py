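import numpy as np
import pytest

from fluctfem.meshkit import (MeshError, TetMesh, element_volume,
                              element_geometry, extract_surface, load_mesh,
                              make_cube_mesh, make_cylinder_mesh,
                              make_sphere_mesh, save_mesh)


def surface_euler_characteristic(mesh):
    faces = mesh.surface_faces
    verts = set(faces.ravel().tolist())
    edges = set()
    for f in faces:
        for i in range(3):
            edges.add(tuple(sorted((int(f[i]), int(f[(i + 1) % 3])))))
    return len(verts) - len(edges) + len(faces)


class TestElementVolume:
    def test_unit_right_tet(self, unit_tet_mesh):
        assert element_volume(unit_tet_mesh, 0) == pytest.approx(1.0 / 6.0)

    def test_regular_tet_edge_one(self):
        # Closed form: V = 1 / (6 sqrt(2)) for a regular tet of edge 1.
        nodes = np.array([
            [1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]
        ]) / (2.0 * np.sqrt(2.0))
        mesh = TetMesh(nodes, np.array([[0, 1, 2, 3]]))
        assert element_volume(mesh, 0) == pytest.approx(1.0 / (6 * np.sqrt(2)))

    def test_coplanar_points_rejected(self):
        nodes = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]])
        with pytest.raises(MeshError, match="degenerate"):
            TetMesh(nodes, np.array([[0, 1, 2, 3]]))


class TestOrientationAndSurface:
    def test_negative_orientation_fixed(self):
        nodes = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
        mesh = TetMesh(nodes, np.array([[0, 2, 1, 3]]))   # inverted order
        assert mesh.signed_volumes()[0] > 0

    def test_single_tet_has_four_faces(self, unit_tet_mesh):
        faces, owners = extract_surface(unit_tet_mesh)
        assert len(faces) == 4
        assert (owners == 0).all()

    def test_two_glued_tets_share_a_face(self):
        nodes = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0],
                          [0, 0, 1], [1, 1, 1]])
        mesh = TetMesh(nodes, np.array([[0, 1, 2, 3], [1, 2, 3, 4]]))
        faces, _ = extract_surface(mesh)
        assert len(faces) == 6
        keys = {tuple(sorted(f)) for f in faces.tolist()}
        assert (1, 2, 3) not in keys

    def test_surface_normals_point_outward(self, cube_mesh):
        geom_c = cube_mesh.nodes.mean(axis=0)
        x = cube_mesh.nodes
        for f in cube_mesh.surface_faces:
            tri = x[f]
            n = np.cross(tri[1] - tri[0], tri[2] - tri[0])
            assert np.dot(n, tri.mean(axis=0) - geom_c) > 0

    def test_non_manifold_rejected(self):
        nodes = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1],
                          [0, 0, -1], [0.3, 0.3, 2.0]])
        elements = np.array([[0, 1, 2, 3], [0, 1, 2, 4], [0, 1, 2, 5]])
        with pytest.raises(MeshError, match="non-manifold"):
            TetMesh(nodes, elements)

    @pytest.mark.parametrize("mesh_factory", [
        lambda: make_cube_mesh(2.0, 2),
        lambda: make_sphere_mesh(5.0, 2.5),
        lambda: make_cylinder_mesh(20.0, 5.0, 2.5),
    ])
    def test_fixture_surfaces_are_closed(self, mesh_factory):
        mesh = mesh_factory()
        # Closed orientable genus-0 surface: V - E + F = 2, and every edge
        # is shared by exactly two surface faces.
        assert surface_euler_characteristic(mesh) == 2
        counts = {}
        for f in mesh.surface_faces:
            for i in range(3):
                e = tuple(sorted((int(f[i]), int(f[(i + 1) % 3]))))
                counts[e] = counts.get(e, 0) + 1
        assert set(counts.values()) == {2}


class TestFixtures:
    def test_cube_single_cell_volume_exact(self):
        mesh = make_cube_mesh(1.0, 1)
        assert mesh.n_elements == 6
        assert mesh.signed_volumes().sum() == pytest.approx(1.0, abs=1e-14)

    def test_cube_volume_exact_any_resolution(self):
        mesh = make_cube_mesh(3.0, 3)
        assert mesh.signed_volumes().sum() == pytest.approx(27.0, rel=1e-13)

    def test_sphere_volume(self):
        mesh = make_sphere_mesh(5.0, 2.0)
        analytic = 4.0 / 3.0 * np.pi * 125.0
        assert mesh.signed_volumes().sum() == pytest.approx(analytic, rel=0.05)

    def test_cylinder_bounding_box(self):
        mesh = make_cylinder_mesh(160.0, 10.0, 2.5)
        lo = mesh.nodes.min(axis=0)
        hi = mesh.nodes.max(axis=0)
        assert hi[2] - lo[2] == pytest.approx(160.0)
        # Cross-section inflated to match area pi R^2, so the box is
        # slightly wider than 20 nm.
        assert hi[0] - lo[0] == pytest.approx(20.0, rel=0.05)
        assert hi[1] - lo[1] == pytest.approx(20.0, rel=0.05)

    def test_bad_parameters_rejected(self):
        with pytest.raises(MeshError):
            make_sphere_mesh(5.0, 11.0)
        with pytest.raises(MeshError):
            make_cylinder_mesh(10.0, 5.0, 12.0)
        with pytest.raises(MeshError):
            make_cube_mesh(-1.0, 1)


class TestShapeGradients:
    def test_gradients_sum_to_zero_and_volumes_match(self):
        mesh = make_sphere_mesh(5.0, 2.5)
        geom = element_geometry(mesh)
        assert np.abs(geom.shape_gradients.sum(axis=1)).max() < 1e-12
        assert geom.volumes.sum() == pytest.approx(
            mesh.signed_volumes().sum())


class TestIO:
    def test_round_trip(self, tmp_path):
        mesh = make_cube_mesh(2.0, 2)
        mesh.face_types[:3] = [1, 2, -1]
        base = str(tmp_path / "cube")
        save_mesh(mesh, base)
        back = load_mesh(base + ".node", base + ".ele", base + ".face")
        np.testing.assert_array_equal(mesh.nodes, back.nodes)
        np.testing.assert_array_equal(mesh.elements, back.elements)
        np.testing.assert_array_equal(mesh.face_types, back.face_types)

    def test_surface_recomputed_without_face_file(self, tmp_path):
        mesh = make_cube_mesh(2.0, 1)
        base = str(tmp_path / "c")
        save_mesh(mesh, base)
        back = load_mesh(base + ".node", base + ".ele")
        assert len(back.surface_faces) == len(mesh.surface_faces)

    def test_zero_based_indexing_detected(self, tmp_path):
        node = tmp_path / "t.node"
        ele = tmp_path / "t.ele"
        node.write_text("4 3 0 0\n0 0 0 0\n1 1 0 0\n2 0 1 0\n3 0 0 1\n")
        ele.write_text("1 4 0\n0 0 1 2 3\n")
        mesh = load_mesh(str(node), str(ele))
        assert mesh.n_nodes == 4 and mesh.n_elements == 1

    def test_malformed_header_reports_line(self, tmp_path):
        node = tmp_path / "bad.node"
        node.write_text("x y z\n")
        with pytest.raises(MeshError, match="bad.node:1"):
            load_mesh(str(node), str(node))

    def test_out_of_range_index_rejected(self, tmp_path):
        node = tmp_path / "t.node"
        ele = tmp_path / "t.ele"
        node.write_text("4 3 0 0\n1 0 0 0\n2 1 0 0\n3 0 1 0\n4 0 0 1\n")
        ele.write_text("1 4 0\n1 1 2 3 9\n")
        with pytest.raises(MeshError, match="out of range"):
            load_mesh(str(node), str(ele))
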