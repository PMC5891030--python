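import numpy as np
import pytest

from fluctfem.constants import NM
from fluctfem.continuum import ContinuumModel
from fluctfem.interactions import (BeadSet, InteractionSet, LJParamMatrix,
                                   Spring, VoxelGrid, _lj_kernel,
                                   candidate_face_pairs, lj_face_forces,
                                   spring_forces, steric_forces,
                                   tet_intersection_volume,
                                   tet_intersection_volume_centroid)
from fluctfem.materials import DEFAULT_TEST_MATERIAL, DragModel
from fluctfem.meshkit import make_cube_mesh

UNIT_TET = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])


class TestTetIntersection:
    def test_identical_tets(self):
        assert tet_intersection_volume(UNIT_TET, UNIT_TET) == \
            pytest.approx(1.0 / 6.0)

    def test_disjoint(self):
        assert tet_intersection_volume(UNIT_TET, UNIT_TET + 10.0) == 0.0

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            ta = rng.standard_normal((4, 3))
            tb = ta * 0.6 + 0.4 * rng.standard_normal((4, 3)) + 0.05
            va = tet_intersection_volume(ta, tb)
            vb = tet_intersection_volume(tb, ta)
            # Sliver intersections amplify clipping roundoff; agreement at
            # 1e-5 relative is far below any force-level tolerance.
            assert va == pytest.approx(vb, rel=1e-5, abs=1e-12)

    def test_nested_tet_exact(self):
        inner = UNIT_TET * 0.5 + 0.1
        assert tet_intersection_volume(inner, UNIT_TET) == \
            pytest.approx(0.5**3 / 6.0, rel=1e-12)

    @pytest.mark.parametrize("shift", [0.1, 0.3, 0.5])
    def test_translated_overlap_vs_monte_carlo(self, shift):
        """Clipping agrees with point-sampling on translated unit tets."""
        ta, tb = UNIT_TET, UNIT_TET + np.array([shift, 0, 0])
        v = tet_intersection_volume(ta, tb)
        rng = np.random.default_rng(1234)
        lo = np.maximum(ta.min(0), tb.min(0))
        hi = np.minimum(ta.max(0), tb.max(0))
        pts = rng.uniform(lo, hi, size=(1000000, 3))

        def inside(tet, p):
            T = np.column_stack([tet[1] - tet[0], tet[2] - tet[0],
                                 tet[3] - tet[0]])
            w = np.linalg.solve(T, (p - tet[0]).T).T
            return (w >= -1e-12).all(1) & (w.sum(1) <= 1 + 1e-12)

        mc = (inside(ta, pts) & inside(tb, pts)).mean() * np.prod(hi - lo)
        assert v == pytest.approx(mc, rel=5e-3)

    def test_degenerate_input_returns_zero(self):
        flat = UNIT_TET.copy()
        flat[3] = [0.5, 0.5, 1e-18]      # coplanar within tolerance
        with pytest.warns(UserWarning):
            v, _ = tet_intersection_volume_centroid(flat, UNIT_TET)
        assert v == 0.0

    def test_centroid_of_full_overlap(self):
        v, c = tet_intersection_volume_centroid(UNIT_TET, UNIT_TET)
        np.testing.assert_allclose(c, UNIT_TET.mean(axis=0), atol=1e-12)


class TestVoxelGrid:
    def _random_faces(self, rng, n=200, box=10.0):
        cents = rng.uniform(0, box, size=(n, 3))
        normals = rng.standard_normal((n, 3))
        types = rng.integers(-1, 7, size=n)
        blobs = rng.integers(0, 2, size=n)
        return cents, normals, types, blobs

    def test_two_facing_faces_pair(self):
        grid = VoxelGrid(1.0)
        cents = np.array([[0.1, 0.1, 0.1], [0.2, 0.1, 0.1]])
        normals = np.array([[1.0, 0, 0], [-1.0, 0, 0]])
        grid.build(cents)
        pairs = candidate_face_pairs(grid, cents, normals, [0, 0], [0, 1])
        assert pairs == [(0, 1)]

    def test_aligned_normals_filtered(self):
        grid = VoxelGrid(1.0)
        cents = np.array([[0.1, 0.1, 0.1], [0.2, 0.1, 0.1]])
        normals = np.array([[1.0, 0, 0], [1.0, 0, 0]])
        grid.build(cents)
        assert candidate_face_pairs(grid, cents, normals, [0, 0],
                                    [0, 1]) == []

    def test_inactive_faces_filtered(self):
        grid = VoxelGrid(1.0)
        cents = np.array([[0.1, 0.1, 0.1], [0.2, 0.1, 0.1]])
        normals = np.array([[1.0, 0, 0], [-1.0, 0, 0]])
        grid.build(cents)
        assert candidate_face_pairs(grid, cents, normals, [-1, 0],
                                    [0, 1]) == []

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_brute_force(self, trial):
        """Linked-cell pair set equals O(N^2) enumeration with the same
        filters, for pairs within the voxel neighbourhood range."""
        rng = np.random.default_rng(100 + trial)
        cents, normals, types, blobs = self._random_faces(rng)
        size = 2.0
        grid = VoxelGrid(size)
        grid.build(cents)
        got = set(candidate_face_pairs(grid, cents, normals, types, blobs))
        keys = np.floor(cents / size).astype(int)
        brute = set()
        for i in range(len(cents)):
            for j in range(i + 1, len(cents)):
                if np.abs(keys[i] - keys[j]).max() > 1:
                    continue
                if types[i] < 0 or types[j] < 0:
                    continue
                if blobs[i] == blobs[j]:
                    continue
                if np.dot(normals[i], normals[j]) >= 0:
                    continue
                brute.add((i, j))
        assert got == brute


class TestStericForces:
    def test_disjoint_pair_no_force(self):
        xa = UNIT_TET * NM
        xb = UNIT_TET * NM + 10 * NM
        fa, fb, en, vol = steric_forces([((0, 1, 2, 3), (0, 1, 2, 3))],
                                        xa, xb, 1e6)
        assert en == 0.0 and vol == 0.0
        assert not fa.any() and not fb.any()

    def test_newtons_third_law(self):
        xa = UNIT_TET * NM
        xb = (UNIT_TET + 0.25) * NM
        fa, fb, en, vol = steric_forces([((0, 1, 2, 3), (0, 1, 2, 3))],
                                        xa, xb, 1e6)
        assert en > 0
        np.testing.assert_allclose(fa.sum(axis=0), -fb.sum(axis=0),
                                   rtol=1e-9)

    def test_gradient_consistency(self):
        """Energy change under a rigid displacement matches -F . delta."""
        k = 1e6
        xa = UNIT_TET * NM
        xb = (UNIT_TET + np.array([0.3, 0.1, 0.05])) * NM
        pairs = [((0, 1, 2, 3), (0, 1, 2, 3))]
        fa, _, e0, _ = steric_forces(pairs, xa, xb, k)
        delta = np.array([1.0, -0.5, 0.3]) * 1e-4 * NM
        _, _, e1, _ = steric_forces(pairs, xa + delta, xb, k)
        work = -(fa.sum(axis=0) @ delta)
        assert e1 - e0 == pytest.approx(work, rel=1e-3)


class TestLJ:
    def test_kernel_zero_at_equilibrium(self):
        f, u = _lj_kernel(2e-9, 2e-9, 1.0, steric_mode=False)
        assert f == pytest.approx(0.0, abs=1e-12)
        assert u == pytest.approx(-1.0)

    def test_transition_continuous_at_req(self):
        """Cubic branch matches the LJ branch in value and slope at r_eq."""
        r_eq, eps = 2e-9, 3.0
        # Value continuity: both branches vanish in force and equal -eps in
        # energy at r = r_eq.
        f_in, u_in = _lj_kernel(r_eq, r_eq, eps, steric_mode=True)
        f_out, u_out = _lj_kernel(r_eq, r_eq, eps, steric_mode=False)
        assert f_in == pytest.approx(f_out, abs=1e-12 * eps / r_eq)
        assert u_in == pytest.approx(-eps) and u_out == pytest.approx(-eps)
        # Slope continuity: one-sided finite differences agree.
        h = 1e-6 * r_eq
        s_in = (f_in - _lj_kernel(r_eq - h, r_eq, eps, True)[0]) / h
        s_out = (_lj_kernel(r_eq + h, r_eq, eps, False)[0] - f_out) / h
        assert s_in == pytest.approx(s_out, rel=1e-4)
        assert s_in == pytest.approx(-72.0 * eps / r_eq**2, rel=1e-4)
        # And zero value/slope at r = 0.
        f0, _ = _lj_kernel(1e-30, r_eq, eps, steric_mode=True)
        assert f0 == pytest.approx(0.0, abs=1e-30)

    def test_parallel_faces_at_equilibrium_distance(self):
        tri = np.array([[0.0, 0, 0], [1e-9, 0, 0], [0, 1e-9, 0]])
        r_eq = 2e-9
        faces_a = {0: (0, 1, 2)}
        faces_b = {0: (0, 1, 2)}
        xa = tri
        xb = tri + np.array([0, 0, r_eq])
        params = LJParamMatrix(cutoff=5e-9)
        params.set_pair(0, 0, r_eq, 4.0)
        fa, fb, en = lj_face_forces([(0, 0)], faces_a, faces_b, xa, xb,
                                    [(0, 0)], params)
        # Kernel root at r_eq: no normal force from centroid quadrature.
        assert np.abs(fa).max() == pytest.approx(0.0, abs=1e-25)
        # Energy density -eps times the two areas.
        area = 0.5e-18
        assert en == pytest.approx(-4.0 * area * area, rel=1e-12)

    def test_beyond_cutoff_zero(self):
        tri = np.array([[0.0, 0, 0], [1e-9, 0, 0], [0, 1e-9, 0]])
        params = LJParamMatrix(cutoff=3e-9)
        params.set_pair(0, 0, 2e-9, 4.0)
        fa, fb, en = lj_face_forces(
            [(0, 0)], {0: (0, 1, 2)}, {0: (0, 1, 2)}, tri,
            tri + np.array([0, 0, 10e-9]), [(0, 0)], params)
        assert en == 0.0 and not fa.any()


class TestSprings:
    def test_rest_length_no_force(self):
        xs = [np.array([[0.0, 0, 0]]), np.array([[2e-9, 0, 0]])]
        springs = [Spring(0, 0, 1, 0, 0.01, 2e-9)]
        forces, en = spring_forces(springs, xs)
        assert en == pytest.approx(0.0)
        assert np.abs(forces[0]).max() < 1e-25

    def test_extension_force_kx(self):
        k, l0, x = 0.01, 2e-9, 0.5e-9
        xs = [np.array([[0.0, 0, 0]]), np.array([[l0 + x, 0, 0]])]
        forces, en = spring_forces([Spring(0, 0, 1, 0, k, l0)], xs)
        assert forces[0][0, 0] == pytest.approx(k * x)
        assert forces[1][0, 0] == pytest.approx(-k * x)
        assert en == pytest.approx(0.5 * k * x**2)

    def test_coincident_endpoints_skipped(self):
        xs = [np.array([[0.0, 0, 0]]), np.array([[0.0, 0, 0]])]
        with pytest.warns(UserWarning):
            forces, en = spring_forces([Spring(0, 0, 1, 0, 0.01, 1e-9)], xs)
        assert en == 0.0

    def test_identical_endpoints_rejected(self):
        with pytest.raises(ValueError):
            Spring(0, 3, 0, 3, 1.0, 0.0)


class TestBeads:
    def _two_cube_models(self):
        mesh = make_cube_mesh(2.0, 1)
        models = []
        for dx in (0.0, 5.0):
            m = ContinuumModel(mesh, DEFAULT_TEST_MATERIAL, DragModel())
            models.append(m)
        return models

    def test_energy_matches_table_interpolation(self):
        models = self._two_cube_models()
        # Bead in blob 0 at origin-ish, bead in blob 1; blob 1 positions
        # shifted +5 nm at compute time.
        table = np.array([[0.0, 0.0, 5.0], [4e-9, 1e-12, 1.0],
                          [8e-9, 0.0, 0.0]])
        beads = BeadSet(
            bead_positions=[[0.0, 0, 0], [0.0, 0, 0]],
            bead_types=[0, 0], bead_blobs=[0, 1], models=models,
            tables={(0, 0): table},
        )
        xs = [models[0].reference_positions,
              models[1].reference_positions + np.array([5e-9, 0, 0])]
        forces, en = beads.compute(xs)
        # r = 5 nm: linear interpolation between table rows 2 and 3.
        frac = (5e-9 - 4e-9) / (8e-9 - 4e-9)
        assert en == pytest.approx((1 - frac) * 1.0 + frac * 0.0)
        fmag = (1 - frac) * 1e-12
        assert forces[0].sum(axis=0)[0] == pytest.approx(-fmag, rel=1e-9)

    def test_same_element_beads_excluded(self):
        models = self._two_cube_models()[:1]
        table = np.array([[0.0, 1e-9, 1.0], [10e-9, 1e-9, 0.0]])
        beads = BeadSet(
            bead_positions=[[0.1, 0, 0], [0.2, 0, 0]],
            bead_types=[0, 0], bead_blobs=[0, 0], models=models,
            tables={(0, 0): table},
        )
        if beads.host_element[0] == beads.host_element[1]:
            forces, en = beads.compute([models[0].reference_positions])
            assert en == 0.0

    def test_missing_table_is_null(self):
        models = self._two_cube_models()
        beads = BeadSet(
            bead_positions=[[0.0, 0, 0], [0.0, 0, 0]],
            bead_types=[0, 1], bead_blobs=[0, 1], models=models,
            tables={},
        )
        xs = [m.reference_positions for m in models]
        forces, en = beads.compute(xs)
        assert en == 0.0

    def test_weights_sum_to_one(self):
        models = self._two_cube_models()[:1]
        beads = BeadSet(
            bead_positions=[[0.3, -0.2, 0.5]], bead_types=[0],
            bead_blobs=[0], models=models, tables={},
        )
        assert beads.weights.sum() == pytest.approx(1.0)


class TestInteractionSet:
    def test_global_newtons_third_law(self):
        mesh = make_cube_mesh(2.0, 1)
        models = [ContinuumModel(mesh, DEFAULT_TEST_MATERIAL, DragModel())
                  for _ in range(2)]
        inter = InteractionSet(models, steric=True, k_steric=1e6,
                               springs=[Spring(0, 0, 1, 7, 1e-3, 0.0)])
        xs = [models[0].reference_positions,
              models[1].reference_positions + np.array([1.2e-9, 0.3e-9, 0])]
        forces, en = inter.compute(xs, step=0)
        total = forces[0].sum(axis=0) + forces[1].sum(axis=0)
        scale = sum(np.abs(f).sum() for f in forces)
        assert np.abs(total).max() < 1e-12 * scale

    def test_steric_energy_partition_invariance(self):
        """Steric energy is symmetric under swapping which body is A."""
        mesh = make_cube_mesh(2.0, 1)
        models = [ContinuumModel(mesh, DEFAULT_TEST_MATERIAL, DragModel())
                  for _ in range(2)]
        shift = np.array([1.4e-9, 0.2e-9, 0.1e-9])
        inter = InteractionSet(models, steric=True, k_steric=1e6)
        e_ab = inter.compute([models[0].reference_positions,
                              models[1].reference_positions + shift], 0)[1]
        inter2 = InteractionSet(models, steric=True, k_steric=1e6)
        e_ba = inter2.compute([models[0].reference_positions + shift,
                               models[1].reference_positions], 0)[1]
        assert e_ab == pytest.approx(e_ba, rel=1e-9)
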