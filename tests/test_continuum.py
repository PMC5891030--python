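import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from fluctfem.constants import K_B, NM
from fluctfem.continuum import ContinuumModel, InvertedElementError
from fluctfem.materials import (DEFAULT_TEST_MATERIAL, DragModel, Material,
                                from_young_poisson)
from fluctfem.meshkit import TetMesh, make_cube_mesh, make_cylinder_mesh

RNG = np.random.default_rng(42)


class TestKinematics:
    def test_reference_is_identity(self, cube_model):
        F = cube_model.deformation_gradients(
            cube_model.reference_positions)
        np.testing.assert_allclose(F, np.broadcast_to(np.eye(3), F.shape), atol=1e-12)

    def test_uniform_scaling(self, cube_model):
        s = 1.1
        F = cube_model.deformation_gradients(
            s * cube_model.reference_positions)
        np.testing.assert_allclose(F, np.broadcast_to(s * np.eye(3), F.shape), atol=1e-12)
        state = cube_model.deformation_gradient(
            s * cube_model.reference_positions, 0)
        assert state.J == pytest.approx(s**3)

    def test_simple_shear(self, cube_model):
        gamma = 0.1
        x = cube_model.reference_positions.copy()
        x[:, 0] += gamma * x[:, 1]
        F = cube_model.deformation_gradients(x)
        expected = np.eye(3)
        expected[0, 1] = gamma
        np.testing.assert_allclose(F, np.broadcast_to(expected, F.shape), atol=1e-12)

    def test_inverted_element_flagged(self, cube_model):
        x = cube_model.reference_positions.copy()
        x[:, 0] *= -1.0
        with pytest.raises(InvertedElementError):
            cube_model.elastic_forces(x)


class TestElasticForces:
    def test_zero_at_reference(self, cube_model):
        f = cube_model.elastic_forces(cube_model.reference_positions)
        assert np.abs(f).max() < 1e-20
        assert cube_model.strain_energy(
            cube_model.reference_positions) == pytest.approx(0.0, abs=1e-25)

    def test_frame_invariance(self, cube_model):
        x = cube_model.reference_positions.copy()
        x += 0.02 * NM * RNG.standard_normal(x.shape)
        U0 = cube_model.strain_energy(x)
        R = Rotation.from_rotvec([0.3, -0.5, 0.9]).as_matrix()
        t = np.array([3.0, -2.0, 1.0]) * NM
        xr = x @ R.T + t
        U1 = cube_model.strain_energy(xr)
        assert U1 == pytest.approx(U0, rel=1e-9)
        f = cube_model.elastic_forces(x)
        fr = cube_model.elastic_forces(xr)
        np.testing.assert_allclose(fr, f @ R.T,
                                   atol=1e-9 * np.abs(f).max())

    def test_force_is_negative_energy_gradient(self, cube_model):
        x = cube_model.reference_positions.copy()
        x += 0.05 * NM * RNG.standard_normal(x.shape)
        dx = 1e-6 * NM * RNG.standard_normal(x.shape)
        U0 = cube_model.strain_energy(x)
        U1 = cube_model.strain_energy(x + dx)
        f = cube_model.elastic_forces(x + 0.5 * dx)
        assert U1 - U0 == pytest.approx(-(f * dx).sum(), rel=1e-6)

    def test_net_force_and_torque_vanish(self, cube_model):
        x = cube_model.reference_positions.copy()
        x += 0.05 * NM * RNG.standard_normal(x.shape)
        f = cube_model.elastic_forces(x)
        scale = np.abs(f).sum()
        assert np.abs(f.sum(axis=0)).max() < 1e-12 * scale
        torque = np.cross(x, f).sum(axis=0)
        assert np.abs(torque).max() < 1e-12 * scale * np.abs(x).max()

    def test_quadratic_energy_limit(self, cube_model):
        # U(2 eps) / U(eps) -> 4 as eps -> 0 for any deformation direction.
        direction = RNG.standard_normal(
            cube_model.reference_positions.shape)
        # eps small enough for the quadratic limit but large enough that
        # the deviatoric invariant (a difference of O(1) terms) is not
        # drowned by roundoff.
        eps = 1e-5
        x0 = cube_model.reference_positions
        u1 = cube_model.strain_energy(x0 + eps * direction * NM)
        u2 = cube_model.strain_energy(x0 + 2 * eps * direction * NM)
        assert u2 / u1 == pytest.approx(4.0, rel=1e-4)

    def test_small_strain_moduli_recovered(self):
        """Linearisation reproduces the input (G, K) on the cube fixture."""
        mesh = make_cube_mesh(2.0, 1)
        G, K = 0.4e9, 1.2e9
        model = ContinuumModel(mesh, Material(1500, G, K, 1e-3, 1e-3))
        V = mesh.signed_volumes().sum() * NM**3
        x0 = model.reference_positions
        # Pure dilation: W = (9K/2) e^2 per volume.
        e = 1e-6
        U = model.strain_energy(x0 * (1 + e))
        assert U / (V * 4.5 * K * e**2) == pytest.approx(1.0, rel=1e-2)
        # Simple shear: W = (G/2) gamma^2 per volume.
        gamma = 1e-6
        x = x0.copy()
        x[:, 0] += gamma * x[:, 1]
        U = model.strain_energy(x)
        assert U / (V * 0.5 * G * gamma**2) == pytest.approx(1.0, rel=1e-2)

    def test_uniaxial_stress_on_cylinder(self):
        """End reaction of a uniaxially stressed cylinder equals E A eps."""
        mesh = make_cylinder_mesh(20.0, 5.0, 2.5)
        E, nu = 1.0e9, 0.35
        model = ContinuumModel(
            mesh, Material.from_young_poisson(1500, E, nu, 1e-3, 1e-3))
        eps = 1e-4
        x = model.reference_positions.copy()
        x[:, 2] *= (1 + eps)
        x[:, :2] *= (1 - nu * eps)
        f = model.elastic_forces(x)
        z = mesh.nodes[:, 2]
        end = z > z.max() - 1e-9
        reaction = -f[end, 2].sum()      # internal tension resists stretch
        A = np.pi * (5 * NM) ** 2
        assert reaction == pytest.approx(E * A * eps, rel=0.01)


class TestSystemMatrices:
    def test_mass_conservation(self, cube_model):
        M = cube_model.mass_matrix()
        total = cube_model.total_mass()
        # Row sums of the consistent matrix give the lumped masses; their
        # sum is the body mass (per spatial component).
        assert M.sum() / 3.0 == pytest.approx(total)
        Ml = cube_model.mass_matrix(lumped=True)
        assert Ml.diagonal().sum() / 3.0 == pytest.approx(total)

    def test_lumped_entries(self, unit_tet_mesh):
        model = ContinuumModel(unit_tet_mesh, DEFAULT_TEST_MATERIAL)
        Ml = model.mass_matrix(lumped=True)
        expected = 1500.0 * (NM**3 / 6.0) / 4.0
        np.testing.assert_allclose(Ml.diagonal(), expected)

    def test_rigid_translation_kinetic_energy(self, cube_model):
        v = np.tile([1.0, -2.0, 0.5], (cube_model.n_nodes, 1))
        m = cube_model.total_mass()
        expected = 0.5 * m * np.dot([1.0, -2.0, 0.5], [1.0, -2.0, 0.5])
        for lumped in (False, True):
            M = cube_model.mass_matrix(lumped=lumped)
            ke = 0.5 * v.ravel() @ (M @ v.ravel())
            assert ke == pytest.approx(expected, rel=1e-12)

    def test_viscosity_pure_drag_is_diagonal(self, cube_mesh):
        model = ContinuumModel(
            cube_mesh, Material(1500, 1e9, 1e9, 0.0, 0.0),
            DragModel(solvent_viscosity=1e-3, node_radius=1e-9))
        lam = model.viscosity_matrix().toarray()
        np.testing.assert_allclose(lam, np.diag(lam.diagonal()))
        np.testing.assert_allclose(lam.diagonal(), 6 * np.pi * 1e-12)

    def test_sphere_total_drag(self, sphere_model_session):
        """r = R/N per node makes the whole object drag 6 pi R mu."""
        model = sphere_model_session
        total = model.node_drag.sum()
        assert total == pytest.approx(6 * np.pi * 5e-9 * 1e-3, rel=1e-12)

    def test_dissipation_nonnegative(self, cube_model):
        lam = cube_model.viscosity_matrix()
        for _ in range(10):
            v = RNG.standard_normal(lam.shape[0])
            assert v @ (lam @ v) >= 0

    def test_viscosity_symmetric(self, cube_model):
        lam = cube_model.viscosity_matrix()
        assert abs(lam - lam.T).max() < 1e-12 * abs(lam).max()


class TestThermalForces:
    def test_zero_temperature(self, cube_model):
        rng = np.random.default_rng(0)
        f = cube_model.thermal_forces(0.0, 1e-14, rng)
        assert not f.any()

    def test_single_element_zero_net_force_and_torque(self, unit_tet_mesh):
        model = ContinuumModel(unit_tet_mesh, DEFAULT_TEST_MATERIAL,
                               DragModel())      # no solvent noise
        rng = np.random.default_rng(1)
        x = model.reference_positions
        for _ in range(50):
            f = model.thermal_forces(300.0, 1e-14, rng)
            scale = np.abs(f).sum() + 1e-300
            assert np.abs(f.sum(axis=0)).max() < 1e-12 * scale
            torque = np.cross(x, f).sum(axis=0)
            assert np.abs(torque).max() < 1e-12 * scale * np.abs(x).max()

    def test_fdt_covariance(self, cube_model):
        """Sample covariance of N_p matches (2 k_B T / dt) Lambda."""
        T, dt = 300.0, 1e-14
        lam = cube_model.viscosity_matrix().toarray()
        target = 2 * K_B * T / dt * lam
        rng = np.random.default_rng(3)
        n = 100000
        dim = lam.shape[0]
        acc = np.zeros((dim, dim))
        mean = np.zeros(dim)
        block = 10000
        for _ in range(n // block):
            draws = np.stack([
                cube_model.thermal_forces(T, dt, rng).ravel()
                for _ in range(block)])
            acc += draws.T @ draws
            mean += draws.sum(axis=0)
        cov = acc / n
        mean /= n
        scale = np.abs(target).max()
        assert np.abs(cov - target).max() < 0.05 * scale
        # Zero mean within Monte-Carlo error.
        assert np.abs(mean).max() < 5 * np.sqrt(scale / n) * 3

    def test_fused_path_matches_separate_calls(self, cube_model):
        x = cube_model.reference_positions + 0.01 * NM * RNG.standard_normal(
            (cube_model.n_nodes, 3))
        r1 = np.random.default_rng(9)
        r2 = np.random.default_rng(9)
        fused = cube_model.nodal_forces(x, 300.0, 1e-14, r1)
        split = (cube_model.elastic_forces(x)
                 + cube_model.thermal_forces(300.0, 1e-14, r2))
        np.testing.assert_allclose(fused, split, rtol=1e-12, atol=0)
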