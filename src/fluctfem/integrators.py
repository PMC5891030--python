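"""Time integration: overdamped (Brownian) and inertial (Langevin) schemes.

Both schemes advance the discretised equation of motion

    M dv/dt = -Lambda v + E + N + O

by explicit first-order stepping.  The Langevin scheme updates velocities
with forward Euler and positions with the *new* velocity (semi-implicit
Euler, chosen for stability); the Brownian scheme drops the inertial term
and solves ``Lambda v = E + N + O`` each step.  The thermal force N is
drawn once per step (Euler-Maruyama convention) with covariance
``(2 k_B T / dt) Lambda``, so at equilibrium strain and kinetic energies
equipartition.

Pinned nodes are removed from the solve by constraint elimination.  Every
body owns an independent, serialisable random stream, which makes restarts
bit-reproducible and per-body results independent of scheduling.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .constants import K_B, NM, NS
from .continuum import ContinuumModel
from .trajectory import Measurements, Trajectory, save_checkpoint

__all__ = ["SimBlob", "Simulator", "SimulationUnstableError", "CentroidTracker"]


class CentroidTracker:
    """Records a weighted node centroid of blob 0 after every step.

    Used by the diffusion estimators, which need per-step resolution
    without writing every frame.  ``weights`` are per-node and are
    normalised internally; pass the lumped node masses for a mass centroid
    or the node drags for the drag-weighted (exactly diffusing) centroid.
    """

    def __init__(self, weights):
        w = np.asarray(weights, dtype=float)
        self.weights = w / w.sum()
        self._chunks = []

    def __call__(self, sim):
        x = sim.blobs[0].positions
        self._chunks.append((self.weights[:, None] * x).sum(axis=0)[None, :])

    def extend(self, arr):
        self._chunks.append(np.array(arr))

    @property
    def positions(self) -> np.ndarray:
        """(steps, 3) centroid positions in metres."""
        return np.concatenate(self._chunks, axis=0)

# Above this many free degrees of freedom, switch from a dense factor to
# a sparse LU for the per-step solves.
_DENSE_DOF_LIMIT = 1500


class SimulationUnstableError(RuntimeError):
    pass


class _Solver:
    """Linear solver with a precomputed factorisation (dense or sparse)."""

    def __init__(self, A: sp.spmatrix):
        n = A.shape[0]
        if n <= _DENSE_DOF_LIMIT:
            self._inv = np.linalg.inv(A.toarray())
            self._lu = None
        else:
            self._inv = None
            self._lu = spla.splu(A.tocsc())

    def solve(self, b: np.ndarray) -> np.ndarray:
        if self._inv is not None:
            return self._inv @ b
        return self._lu.solve(b)


class SimBlob:
    """One simulated body: mechanical model + scheme + constraints.

    Parameters
    ----------
    model : ContinuumModel
    scheme : {"brownian", "langevin"}
    pinned : sequence of node indices frozen in place
    lumped_mass : use the lumped (diagonal) mass matrix in the Langevin solve
    positions : optional (N, 3) initial positions in metres
    velocities : optional (N, 3) initial velocities in m/s (Langevin)
    """

    def __init__(self, model: ContinuumModel, scheme: str = "brownian",
                 pinned=(), lumped_mass: bool = False,
                 positions=None, velocities=None):
        if scheme not in ("brownian", "langevin"):
            raise ValueError(f"unknown scheme {scheme!r}")
        self.model = model
        self.scheme = scheme
        self.pinned = np.asarray(sorted(set(int(p) for p in pinned)), dtype=np.intp)
        if len(self.pinned) and (
            self.pinned.min() < 0 or self.pinned.max() >= model.n_nodes
        ):
            raise ValueError("pinned node index out of range")
        self.lumped_mass = lumped_mass

        n = model.n_nodes
        free = np.ones(n, dtype=bool)
        free[self.pinned] = False
        self.free_dofs = np.flatnonzero(np.repeat(free, 3))

        self.positions = (np.array(positions, dtype=float) if positions is not None
                          else model.reference_positions.copy())
        self.velocities = (np.array(velocities, dtype=float)
                           if velocities is not None else np.zeros((n, 3)))
        self.velocities.reshape(-1)[np.setdiff1d(np.arange(3 * n),
                                                 self.free_dofs)] = 0.0

        lam = model.viscosity_matrix()
        self._lambda = lam.toarray() if 3 * n <= _DENSE_DOF_LIMIT else lam
        if scheme == "brownian":
            lam_red = lam[self.free_dofs][:, self.free_dofs]
            if lam_red.nnz == 0 or abs(lam_red).sum() == 0.0:
                raise ValueError(
                    "Brownian scheme requires a non-singular viscosity matrix: "
                    "enable internal viscosity or solvent drag"
                )
            self._solver = _Solver(lam_red)
            self._mass = None
        else:
            M = model.mass_matrix(lumped=lumped_mass)
            self._mass = M
            self._solver = _Solver(M[self.free_dofs][:, self.free_dofs])
        self._lumped_node_mass = np.asarray(
            model.mass_matrix(lumped=True).diagonal()
        ).reshape(-1, 3)[:, 0]

    @property
    def n_nodes(self) -> int:
        return self.model.n_nodes

    def centre_of_mass(self) -> np.ndarray:
        """Mass centroid (m), lumped node masses as weights."""
        w = self._lumped_node_mass
        return (w[:, None] * self.positions).sum(axis=0) / w.sum()

    def drag_centroid(self) -> np.ndarray:
        """Drag-weighted centroid; the exact diffusing coordinate of the
        overdamped scheme (equals the plain node mean for uniform drag)."""
        w = self.model.node_drag
        if w.sum() == 0:
            w = np.ones_like(w)
        return (w[:, None] * self.positions).sum(axis=0) / w.sum()

    def kinetic_energy(self) -> float:
        if self._mass is None:
            return 0.0
        v = self.velocities.ravel()
        return 0.5 * float(v @ (self._mass @ v))


class Simulator:
    """Integrates a set of blobs forward in time.

    Parameters
    ----------
    blobs : list of SimBlob
    dt : time-step, seconds
    temperature : K (0 disables thermal noise)
    seed : master seed; each blob gets an independent child stream
    interactions : optional object with ``compute(positions_list, step)``
        returning ``(forces_list, energy)`` -- see
        :class:`fluctfem.interactions.InteractionSet`.
    external_forces : optional list of (N_b, 3) arrays or callables
        ``f(positions) -> (N_b, 3)`` giving the conservative force O_p.
    noise : master switch for the thermal force.
    """

    def __init__(self, blobs, dt: float, temperature: float = 300.0,
                 seed: int = 0, interactions=None, external_forces=None,
                 noise: bool = True, on_inversion: str = "abort"):
        if dt <= 0:
            raise ValueError("dt must be positive")
        if on_inversion not in ("abort", "halve_dt_once"):
            raise ValueError("on_inversion must be 'abort' or 'halve_dt_once'")
        self.on_inversion = on_inversion
        self._dt_halved = False
        self.blobs = list(blobs)
        self.dt = float(dt)
        self.temperature = float(temperature)
        self.seed = int(seed)
        self.interactions = interactions
        self.noise = bool(noise) and self.temperature > 0.0
        if external_forces is None:
            external_forces = [None] * len(self.blobs)
        self.external_forces = list(external_forces)
        self.step_index = 0
        self.time = 0.0
        self.rngs = [
            np.random.Generator(np.random.PCG64(
                np.random.SeedSequence([self.seed, b])))
            for b in range(len(self.blobs))
        ]
        self.last_interaction_energy = 0.0

    # ------------------------------------------------------------------

    def _forces(self):
        positions = [b.positions for b in self.blobs]
        if self.interactions is not None:
            inter, self.last_interaction_energy = self.interactions.compute(
                positions, self.step_index
            )
        else:
            inter = None
        out = []
        for i, blob in enumerate(self.blobs):
            if self.noise:
                f = blob.model.nodal_forces(blob.positions, self.temperature,
                                            self.dt, self.rngs[i])
            else:
                f = blob.model.elastic_forces(blob.positions)
            if inter is not None:
                f += inter[i]
            ext = self.external_forces[i]
            if ext is not None:
                f += ext(blob.positions) if callable(ext) else ext
            out.append(f)
        return out

    def step(self) -> None:
        """Advance the whole system by one time-step.

        With ``on_inversion='halve_dt_once'`` a step that inverts an
        element is rejected and retried once at half the time-step (which
        then remains halved); otherwise inversion aborts the run.
        """
        if self.on_inversion == "halve_dt_once" and not self._dt_halved:
            snapshot = [(b.positions.copy(), b.velocities.copy())
                        for b in self.blobs]
            try:
                self._step_once()
                return
            except Exception as exc:
                from .continuum import InvertedElementError
                if not isinstance(exc, InvertedElementError):
                    raise
                for blob, (x, v) in zip(self.blobs, snapshot):
                    blob.positions[...] = x
                    blob.velocities[...] = v
                self.dt /= 2.0
                self._dt_halved = True
        self._step_once()

    def _step_once(self) -> None:
        forces = self._forces()
        dt = self.dt
        for blob, f in zip(self.blobs, forces):
            fd = blob.free_dofs
            if blob.scheme == "brownian":
                v = blob._solver.solve(f.ravel()[fd])
                blob.positions.reshape(-1)[fd] += dt * v
            else:
                vflat = blob.velocities.reshape(-1)
                rhs = f.ravel() - (blob._lambda @ vflat)
                acc = blob._solver.solve(rhs[fd])
                vflat[fd] += dt * acc
                blob.positions.reshape(-1)[fd] += dt * vflat[fd]
        self.step_index += 1
        self.time = self.step_index * dt

    # ------------------------------------------------------------------

    def strain_energy(self) -> float:
        return sum(b.model.strain_energy(b.positions) for b in self.blobs)

    def kinetic_energy(self) -> float:
        return sum(b.kinetic_energy() for b in self.blobs)

    def _has_langevin(self) -> bool:
        return any(b.scheme == "langevin" for b in self.blobs)

    def run(self, n_steps: int, n_check: int = 100,
            trajectory_path=None, measurement_path=None,
            checkpoint_path=None, per_step=None, meta=None):
        """Run ``n_steps`` steps, recording every ``n_check`` steps.

        Returns ``(Trajectory, Measurements)``.  The initial state is always
        recorded as frame 0.  ``per_step`` is an optional callback invoked
        after every step with this simulator (used by diffusion estimators
        that need per-step resolution without storing every frame).
        """
        if n_steps < 0:
            raise ValueError("n_steps must be non-negative")
        langevin = self._has_langevin()
        cols = ["time_ns", "strain_energy"]
        if langevin:
            cols.append("kinetic_energy")
        cols += ["com_x", "com_y", "com_z", "rmsd_nm"]
        meas = Measurements(cols)
        traj = Trajectory(meta=dict(meta or {},
                                    dt_ns=self.dt / NS, n_check=n_check,
                                    seed=self.seed))
        ref = [b.positions.copy() for b in self.blobs]
        expected_u = 1.5 * K_B * max(self.temperature, 1.0) * sum(
            b.n_nodes for b in self.blobs
        )

        def record():
            u = self.strain_energy()
            if not np.isfinite(u):
                raise SimulationUnstableError(
                    f"non-finite energy at step {self.step_index}"
                )
            if self.noise and u > 1.0e3 * expected_u:
                raise SimulationUnstableError(
                    f"energy blow-up at step {self.step_index}: "
                    f"U = {u:.3e} J exceeds 1e3 x equipartition"
                )
            com = self._global_com()
            dev = np.concatenate([
                (b.positions - r0).ravel() for b, r0 in zip(self.blobs, ref)
            ])
            rmsd = np.sqrt(np.mean((dev.reshape(-1, 3) ** 2).sum(axis=1)))
            row = {"time_ns": self.time / NS, "strain_energy": u,
                   "com_x": com[0] / NM, "com_y": com[1] / NM,
                   "com_z": com[2] / NM, "rmsd_nm": rmsd / NM}
            if langevin:
                row["kinetic_energy"] = self.kinetic_energy()
            meas.append(**row)
            traj.append(
                self.time / NS,
                [b.positions / NM for b in self.blobs],
                ([b.velocities / (NM / NS) for b in self.blobs]
                 if langevin else None),
            )

        record()
        runner = self._fast_runner(per_step)
        if runner is not None:
            done = 0
            while done < n_steps:
                m = min(n_check, n_steps - done)
                runner.advance(m)
                done += m
                if done % n_check == 0:
                    record()
        else:
            for k in range(n_steps):
                self.step()
                if per_step is not None:
                    per_step(self)
                if (k + 1) % n_check == 0:
                    record()
        if trajectory_path:
            traj.write(trajectory_path)
        if measurement_path:
            meas.write(measurement_path, meta=traj.meta)
        if checkpoint_path:
            save_checkpoint(checkpoint_path, self.checkpoint())
        return traj, meas

    def _fast_runner(self, per_step):
        """A compiled single-blob runner when the configuration allows it."""
        from . import fastpath

        if not fastpath.HAVE_NUMBA:
            return None
        if self.on_inversion != "abort":
            return None
        if len(self.blobs) != 1 or self.interactions is not None:
            return None
        if any(f is not None for f in self.external_forces):
            return None
        if per_step is not None and not isinstance(per_step, CentroidTracker):
            return None
        blob = self.blobs[0]
        if blob._solver._inv is None:
            return None
        if blob.scheme == "langevin" and not isinstance(blob._lambda, np.ndarray):
            return None
        return fastpath.FastRunner(self, tracker=per_step)

    def _global_com(self) -> np.ndarray:
        ws, xs = [], []
        for b in self.blobs:
            w = b._lumped_node_mass
            ws.append(w.sum())
            xs.append(b.centre_of_mass())
        ws = np.array(ws)
        return (ws[:, None] * np.array(xs)).sum(axis=0) / ws.sum()

    # ------------------------------------------------------------------
    # Restart support
    # ------------------------------------------------------------------

    def checkpoint(self) -> dict:
        return {
            "step": self.step_index,
            "time": self.time,
            "blobs": [
                {
                    "positions": b.positions.copy(),
                    "velocities": (b.velocities.copy()
                                   if b.scheme == "langevin" else None),
                    "rng_state": rng.bit_generator.state,
                }
                for b, rng in zip(self.blobs, self.rngs)
            ],
        }

    def restore(self, state: dict) -> None:
        if len(state["blobs"]) != len(self.blobs):
            raise ValueError("checkpoint blob count does not match system")
        self.step_index = int(state["step"])
        self.time = float(state["time"])
        for blob, rng, entry in zip(self.blobs, self.rngs, state["blobs"]):
            blob.positions[...] = entry["positions"]
            if entry.get("velocities") is not None:
                blob.velocities[...] = entry["velocities"]
            rng.bit_generator.state = entry["rng_state"]
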