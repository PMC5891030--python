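import numpy as np
import pytest

from fluctfem.constants import K_B, NM
from fluctfem.continuum import ContinuumModel
from fluctfem.integrators import CentroidTracker, SimBlob, Simulator
from fluctfem.materials import DEFAULT_TEST_MATERIAL, DragModel, Material
from fluctfem.meshkit import TetMesh, make_cube_mesh
from fluctfem.trajectory import (Trajectory, load_checkpoint,
                                 save_checkpoint)


def single_tet_model(drag_radius=1e-9, viscosities=(1e-3, 1e-3),
                     solvent=1e-3):
    nodes = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
    mesh = TetMesh(nodes, np.array([[0, 1, 2, 3]]))
    mat = Material(1500.0, 1e9, 1e9, *viscosities)
    drag = DragModel(solvent_viscosity=solvent, node_radius=drag_radius,
                     temperature=300.0)
    return ContinuumModel(mesh, mat, drag)


class TestStepping:
    def test_no_forces_state_unchanged(self):
        model = single_tet_model()
        for scheme in ("brownian", "langevin"):
            blob = SimBlob(model, scheme, lumped_mass=True)
            sim = Simulator([blob], dt=1e-14, temperature=0.0, noise=False)
            x0 = blob.positions.copy()
            for _ in range(10):
                sim.step()
            # Elastic forces at the reference are zero to roundoff, so any
            # drift is at the 1e-28 m level.
            np.testing.assert_allclose(blob.positions, x0, atol=1e-20)

    def test_langevin_drag_decay(self):
        """A rigidly moving body decelerates as exp(-lambda t / m)."""
        model = single_tet_model(viscosities=(0.0, 0.0))
        v0 = np.tile([1.0, 0, 0], (4, 1))
        blob = SimBlob(model, "langevin", lumped_mass=True, velocities=v0)
        lam = model.node_drag[0]
        m = model.total_mass() / 4.0        # per node, lumped
        dt = 0.001 * m / lam
        sim = Simulator([blob], dt=dt, temperature=0.0, noise=False)
        n = 500
        for _ in range(n):
            sim.step()
        expected = np.exp(-lam * n * dt / m)
        assert blob.velocities[0, 0] == pytest.approx(expected, rel=5e-3)

    def test_brownian_mobility(self):
        """Constant force F on a rigid blob drifts at F / lambda_total."""
        model = single_tet_model(viscosities=(0.0, 0.0))
        blob = SimBlob(model, "brownian")
        F = 1e-12
        ext = np.zeros((4, 3))
        ext[:, 1] = F / 4.0
        sim = Simulator([blob], dt=1e-12, temperature=0.0, noise=False,
                        external_forces=[ext])
        x0 = blob.positions.copy()
        n = 100
        for _ in range(n):
            sim.step()
        lam_tot = model.node_drag.sum()
        drift = (blob.positions - x0)[:, 1].mean()
        assert drift == pytest.approx(F / lam_tot * n * 1e-12, rel=1e-9)

    def test_brownian_rejects_singular_viscosity(self):
        model = single_tet_model(viscosities=(0.0, 0.0), solvent=0.0)
        with pytest.raises(ValueError, match="non-singular"):
            SimBlob(model, "brownian")

    def test_pinned_nodes_fixed(self):
        model = single_tet_model()
        blob = SimBlob(model, "brownian", pinned=[0, 1])
        sim = Simulator([blob], dt=1e-14, temperature=300.0, seed=4)
        x0 = blob.positions.copy()
        sim.run(200, n_check=200)
        np.testing.assert_array_equal(blob.positions[:2], x0[:2])
        assert not np.array_equal(blob.positions[2:], x0[2:])


class TestRunAndRecording:
    def test_zero_steps_records_initial_frame(self):
        model = single_tet_model()
        sim = Simulator([SimBlob(model, "brownian")], dt=1e-14,
                        temperature=300.0)
        traj, meas = sim.run(0)
        assert traj.n_frames == 1
        assert meas.column("time_ns")[0] == 0.0

    def test_determinism_identical_bytes(self, tmp_path):
        paths = []
        for run in range(2):
            model = single_tet_model()
            sim = Simulator([SimBlob(model, "brownian")], dt=1e-14,
                            temperature=300.0, seed=11)
            p = tmp_path / f"t{run}.ftrj"
            sim.run(300, n_check=50, trajectory_path=p)
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_trajectory_round_trip(self, tmp_path):
        model = single_tet_model()
        # dt must resolve the single tet's viscous relaxation (tiny mass).
        sim = Simulator([SimBlob(model, "langevin", lumped_mass=True)],
                        dt=1e-17, temperature=300.0, seed=2)
        p = tmp_path / "t.ftrj"
        traj, _ = sim.run(100, n_check=25, trajectory_path=p)
        back = Trajectory.read(p)
        assert back.n_frames == traj.n_frames
        np.testing.assert_allclose(back.frames[-1][0], traj.frames[-1][0],
                                   rtol=1e-9)
        np.testing.assert_allclose(back.velocities[-1][0],
                                   traj.velocities[-1][0], rtol=1e-9,
                                   atol=1e-12)

    def test_restart_is_bit_exact(self, tmp_path):
        """A checkpointed run continues exactly as an unbroken one."""
        def fresh():
            model = single_tet_model()
            return Simulator([SimBlob(model, "langevin", lumped_mass=True)],
                             dt=1e-17, temperature=300.0, seed=5)

        unbroken = fresh()
        unbroken.run(1000, n_check=500)

        first = fresh()
        first.run(500, n_check=500)
        ckpt = tmp_path / "c.json"
        save_checkpoint(ckpt, first.checkpoint())

        resumed = fresh()
        resumed.restore(load_checkpoint(ckpt))
        assert resumed.step_index == 500
        resumed.run(500, n_check=500)

        np.testing.assert_array_equal(resumed.blobs[0].positions,
                                      unbroken.blobs[0].positions)
        np.testing.assert_array_equal(resumed.blobs[0].velocities,
                                      unbroken.blobs[0].velocities)

    def test_centroid_tracker_matches_recorded_positions(self):
        model = single_tet_model()
        blob = SimBlob(model, "brownian")
        tracker = CentroidTracker(np.ones(4))
        sim = Simulator([blob], dt=1e-14, temperature=300.0, seed=8)
        sim.run(50, n_check=50, per_step=tracker)
        com = tracker.positions
        assert com.shape == (50, 3)
        np.testing.assert_allclose(com[-1], blob.positions.mean(axis=0),
                                   rtol=1e-12)


class TestFastPathConsistency:
    def test_fast_and_numpy_paths_agree(self):
        """The compiled kernel reproduces the numpy step loop."""
        import fluctfem.fastpath as fp
        if not fp.HAVE_NUMBA:
            pytest.skip("numba unavailable")

        def build():
            mesh = make_cube_mesh(2.0, 2)
            drag = DragModel(solvent_viscosity=1e-3, node_radius=0.3e-9,
                             temperature=300.0)
            model = ContinuumModel(mesh, DEFAULT_TEST_MATERIAL, drag)
            return model

        for scheme in ("brownian", "langevin"):
            sims = []
            for use_fast in (True, False):
                model = build()
                blob = SimBlob(model, scheme, lumped_mass=True)
                sim = Simulator([blob], dt=1e-14, temperature=300.0, seed=3)
                if use_fast:
                    sim.run(200, n_check=200)
                else:
                    orig = fp.HAVE_NUMBA
                    fp.HAVE_NUMBA = False
                    try:
                        sim.run(200, n_check=200)
                    finally:
                        fp.HAVE_NUMBA = orig
                sims.append(sim)
            a = sims[0].blobs[0].positions
            b = sims[1].blobs[0].positions
            np.testing.assert_allclose(a, b, rtol=1e-10, atol=0)


class TestInversionPolicy:
    def test_halve_dt_once_recovers(self):
        """A step that inverts an element is rejected and retried at dt/2."""
        model = single_tet_model()
        # Absurdly large step so the first thermal kick inverts the tet.
        blob = SimBlob(model, "brownian")
        sim = Simulator([blob], dt=1e-6, temperature=300.0, seed=0,
                        on_inversion="halve_dt_once")
        from fluctfem.continuum import InvertedElementError
        try:
            for _ in range(3):
                sim.step()
        except InvertedElementError:
            pass
        assert sim._dt_halved
        assert sim.dt == pytest.approx(0.5e-6)

    def test_default_policy_aborts(self):
        model = single_tet_model()
        blob = SimBlob(model, "brownian")
        sim = Simulator([blob], dt=1e-6, temperature=300.0, seed=0)
        from fluctfem.continuum import InvertedElementError
        with pytest.raises(InvertedElementError):
            for _ in range(10):
                sim.step()
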