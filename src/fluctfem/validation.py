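"""The validation suite: the physical checks shipped with the package.

Every protocol here is a self-contained function returning a dict of
measured quantities; the test suite, the ``selftest`` CLI subcommand and
the acceptance script all call these.  The study conditions are fixed:

* sphere fixture: R = 5 nm, rho = 1500 kg/m^3, E = 1 GPa, nu = 0.35,
  internal and solvent viscosities 1e-3 Pa s, T = 300 K, per-node drag
  radius r = R/N so the whole object has Stokes drag 6 pi R mu;
* cylinder fixture: L = 160 nm, R = 10 nm, E = 600 GPa;
* equipartition runs: dt = 10 fs for 10^5 steps per ns.

Two sphere resolutions are used: the *fine* mesh (edge ~2 nm, N = 185)
for the overdamped protocols, where statistical error dominates, and the
*coarse* mesh (edge ~2.5 nm, N = 85) for the inertial protocols, where
the fixed 10 fs step must resolve the fastest viscous relaxation time
(lambda_max dt < 0.06 on the coarse mesh) for accurate kinetic-energy
statistics.  The inertial runs use the lumped mass matrix: the
generalised spectrum of (viscosity, mass) exceeds the explicit stability
bound with the consistent matrix at this step size.
"""

from __future__ import annotations

import numpy as np

from .analysis import (diffusion_check, energy_convergence, kabsch,
                       pca, rotation_angle)
from .constants import K_B, NM, PS, FS
from .continuum import ContinuumModel
from .integrators import CentroidTracker, SimBlob, Simulator
from .interactions import InteractionSet, Spring
from .materials import DEFAULT_TEST_MATERIAL, DragModel, Material
from .meshkit import make_cube_mesh, make_cylinder_mesh, make_sphere_mesh

__all__ = [
    "sphere_model", "brownian_equipartition", "langevin_equipartition",
    "stretch_test", "bend_test", "brownian_diffusion", "langevin_diffusion",
    "sphere_collision", "cube_pull", "stiffness_scaling", "selftest",
]

TEMPERATURE = 300.0
SPHERE_RADIUS_NM = 5.0
SOLVENT_VISCOSITY = 1.0e-3
DT_EQUIPARTITION = 10.0 * FS
FINE_EDGE_NM = 2.0
COARSE_EDGE_NM = 2.5


def sphere_model(resolution: str = "fine", youngs: float = 1.0e9,
                 solvent: float = SOLVENT_VISCOSITY):
    """The validation sphere with per-node drag radius r = R/N."""
    edge = FINE_EDGE_NM if resolution == "fine" else COARSE_EDGE_NM
    mesh = make_sphere_mesh(SPHERE_RADIUS_NM, edge)
    material = Material.from_young_poisson(1500.0, youngs, 0.35,
                                           1.0e-3, 1.0e-3)
    drag = DragModel(
        solvent_viscosity=solvent,
        node_radius=SPHERE_RADIUS_NM * NM / mesh.n_nodes,
        temperature=TEMPERATURE,
    )
    return ContinuumModel(mesh, material, drag)


def brownian_equipartition(seed: int = 1, t_sim_ns: float = 1.0,
                           equilibration_ns: float = None):
    """Overdamped sphere run vs the equipartition strain energy.

    10^5 steps of 10 fs per ns of simulation; frames are recorded so that
    the last 60 cover most of a 1 ns run.  Returns the last-60-frame mean
    deviation and (for longer runs) the post-equilibration mean deviation
    from k_B T (3N - 6)/2.
    """
    model = sphere_model("fine")
    n_steps = int(round(t_sim_ns * 1e-9 / DT_EQUIPARTITION))
    # ~65 frames for the last-60 protocol on a 1 ns run; for longer runs
    # the cadence is capped at 15 ps so the equilibrated average actually
    # benefits from the added simulation time (the strain energy
    # decorrelates within ~5 ps, so recorded frames are independent).
    n_check = max(1, min(1500, n_steps // 65))
    blob = SimBlob(model, "brownian")
    sim = Simulator([blob], dt=DT_EQUIPARTITION, temperature=TEMPERATURE,
                    seed=seed)
    traj, meas = sim.run(n_steps, n_check=n_check)
    n_dof = 3 * model.n_nodes - 6
    conv = energy_convergence(meas.column("time_ns"),
                              meas.column("strain_energy"),
                              TEMPERATURE, n_dof)
    out = {
        "n_nodes": model.n_nodes,
        "n_steps": n_steps,
        "deviation_last60": conv["relative_deviation"],
        "theory": conv["theory"],
    }
    if equilibration_ns is not None:
        t = meas.column("time_ns")
        u = meas.column("strain_energy")
        sel = t >= equilibration_ns
        out["deviation_equilibrated"] = u[sel].mean() / conv["theory"] - 1.0
    return out


def langevin_equipartition(seed: int = 1, t_sim_ns: float = 1.0):
    """Inertial sphere run: strain and kinetic energy vs equipartition."""
    model = sphere_model("coarse")
    n_steps = int(round(t_sim_ns * 1e-9 / DT_EQUIPARTITION))
    n_check = max(1, n_steps // 65)
    blob = SimBlob(model, "langevin", lumped_mass=True)
    sim = Simulator([blob], dt=DT_EQUIPARTITION, temperature=TEMPERATURE,
                    seed=seed)
    traj, meas = sim.run(n_steps, n_check=n_check)
    N = model.n_nodes
    kT = K_B * TEMPERATURE
    u = meas.column("strain_energy")
    ke = meas.column("kinetic_energy")
    return {
        "n_nodes": N,
        "strain_deviation": u[-60:].mean() / (kT * (3 * N - 6) / 2.0) - 1.0,
        "kinetic_deviation": ke[-60:].mean() / (1.5 * kT * N) - 1.0,
    }


# ---------------------------------------------------------------------------
# Cylinder mechanics
# ---------------------------------------------------------------------------

CYL_LENGTH_NM = 160.0
CYL_RADIUS_NM = 10.0
CYL_YOUNGS = 600.0e9
# The beam tests specify only the Young's modulus; nu = 0 is used so the
# fully clamped end exerts no Poisson constraint on the axial response
# (with nu > 0 the clamp stiffens the measured modulus by ~0.6% at this
# aspect ratio, far above the reference accuracy of the stretch test).
CYL_POISSON = 0.0


def _cylinder_setup(target_edge_nm):
    mesh = make_cylinder_mesh(CYL_LENGTH_NM, CYL_RADIUS_NM, target_edge_nm)
    material = Material.from_young_poisson(1500.0, CYL_YOUNGS, CYL_POISSON,
                                           1.0e-3, 1.0e-3)
    model = ContinuumModel(mesh, material, DragModel())
    z = mesh.nodes[:, 2]
    zmax = z.max()
    pinned = np.flatnonzero(z < 1e-9)
    end_nodes = np.flatnonzero(z > zmax - 1e-9)
    # Area-weighted loading of the free end: each end face spreads a third
    # of its area to each of its nodes (uniform traction).
    weights = np.zeros(mesh.n_nodes)
    x = model.reference_positions
    for f in mesh.surface_faces:
        if all(z[v] > zmax - 1e-9 for v in f):
            tri = x[f]
            area = 0.5 * np.linalg.norm(
                np.cross(tri[1] - tri[0], tri[2] - tri[0]))
            for v in f:
                weights[v] += area / 3.0
    end_area = weights.sum()
    weights /= end_area
    return model, pinned, end_nodes, weights, end_area


def _relax(model, pinned, force, max_iter=50, tol=1e-10):
    """Quasi-static equilibrium of the noise-free loaded body.

    Newton iteration on the full nonlinear elastic force with the
    reference-configuration stiffness as (constant) Jacobian; for the
    small-strain validation loads this converges in one or two steps to
    the same equilibrium a noise-free dynamic relaxation reaches.
    """
    import scipy.sparse.linalg as spla

    blob = SimBlob(model, "brownian", pinned=pinned)
    fd = blob.free_dofs
    K = model.stiffness_matrix()[fd][:, fd].tocsc()
    lu = spla.splu(K)
    x = blob.positions
    fext = force.ravel()[fd]
    fscale = np.abs(fext).max()
    for _ in range(max_iter):
        res = model.elastic_forces(x).ravel()[fd] + fext
        if np.abs(res).max() < tol * fscale:
            break
        x.reshape(-1)[fd] += lu.solve(res)
    return blob


def stretch_test(force_pN: float = 10.0, target_edge_nm: float = 2.0):
    """Axial stretch of the pinned cylinder; recovers Young's modulus.

    E_meas = F L0 / (A0 dL) with A0 the analytic cross-section pi R^2 (the
    mesh section is inflated at build time to that area) and dL the
    area-weighted mean axial displacement of the loaded end.
    """
    model, pinned, end_nodes, w, end_area = _cylinder_setup(target_edge_nm)
    F = force_pN * 1e-12
    ext = np.zeros((model.n_nodes, 3))
    ext[:, 2] = F * w
    blob = _relax(model, pinned, ext)
    dz = (w[end_nodes] / w[end_nodes].sum()) @ (
        blob.positions[end_nodes, 2]
        - model.reference_positions[end_nodes, 2])
    L0 = CYL_LENGTH_NM * NM
    A0 = np.pi * (CYL_RADIUS_NM * NM) ** 2
    E_meas = F * L0 / (A0 * dz)
    return {
        "E_measured": E_meas,
        "relative_error": E_meas / CYL_YOUNGS - 1.0,
        "n_nodes": model.n_nodes,
    }


def bend_test(force_pN: float = 1.0, target_edge_nm: float = 2.0):
    """Perpendicular tip load on the pinned cylinder; flexural rigidity.

    EI_meas = F L^3 / (3 dy) from the tip deflection, against the analytic
    E pi R^4 / 4.  The error is dominated by the stiffness of linear
    elements in bending and decreases with mesh refinement.
    """
    model, pinned, end_nodes, w, _ = _cylinder_setup(target_edge_nm)
    F = force_pN * 1e-12
    ext = np.zeros((model.n_nodes, 3))
    ext[:, 0] = F * w
    blob = _relax(model, pinned, ext)
    dx = (w[end_nodes] / w[end_nodes].sum()) @ (
        blob.positions[end_nodes, 0]
        - model.reference_positions[end_nodes, 0])
    L = CYL_LENGTH_NM * NM
    EI_meas = F * L**3 / (3.0 * dx)
    EI_theory = CYL_YOUNGS * np.pi * (CYL_RADIUS_NM * NM) ** 4 / 4.0
    return {
        "EI_measured": EI_meas,
        "EI_theory": EI_theory,
        "relative_error": EI_meas / EI_theory - 1.0,
        "n_nodes": model.n_nodes,
    }


# ---------------------------------------------------------------------------
# Diffusion
# ---------------------------------------------------------------------------

def brownian_diffusion(seed: int = 1, t_sim_ns: float = 10.0,
                       dt: float = 0.1 * PS):
    """Free-sphere MSD per step vs 6 k_B T dt / (6 pi R mu).

    The drag-weighted centroid is tracked every step; the first 10% of the
    run is discarded as equilibration.
    """
    model = sphere_model("fine")
    n_steps = int(round(t_sim_ns * 1e-9 / dt))
    blob = SimBlob(model, "brownian")
    tracker = CentroidTracker(model.node_drag)
    sim = Simulator([blob], dt=dt, temperature=TEMPERATURE, seed=seed)
    sim.run(n_steps, n_check=n_steps, per_step=tracker)
    com = tracker.positions[n_steps // 10:]
    lam = 6.0 * np.pi * (SPHERE_RADIUS_NM * NM) * SOLVENT_VISCOSITY
    res = diffusion_check(com, dt, TEMPERATURE, drag=lam)
    res["n_steps"] = n_steps
    res["n_nodes"] = model.n_nodes
    return res


def langevin_diffusion(seed: int = 1, t_sim_ns: float = 10.0,
                       dt: float = 0.1 * PS):
    """Free-sphere ballistic MSD per step vs 3 k_B T dt^2 / m.

    dt is far below the momentum relaxation time m/lambda (~8 ps), so the
    single-step motion is ballistic; the mass centroid is tracked.
    """
    model = sphere_model("coarse")
    n_steps = int(round(t_sim_ns * 1e-9 / dt))
    blob = SimBlob(model, "langevin", lumped_mass=True)
    tracker = CentroidTracker(blob._lumped_node_mass)
    sim = Simulator([blob], dt=dt, temperature=TEMPERATURE, seed=seed)
    sim.run(n_steps, n_check=n_steps, per_step=tracker)
    com = tracker.positions[n_steps // 10:]
    res = diffusion_check(com, dt, TEMPERATURE, mass=model.total_mass())
    res["n_steps"] = n_steps
    res["n_nodes"] = model.n_nodes
    return res


# ---------------------------------------------------------------------------
# Steric repulsion and springs
# ---------------------------------------------------------------------------

def sphere_collision(approach_speed: float = 2.0, gap_nm: float = 0.5,
                     dt: float = 0.25 * PS, t_sim_ns: float = 0.7,
                     k_steric: float = 1.0e6):
    """Two soft spheres collide head-on without noise and rebound.

    Both spheres move at ``approach_speed`` m/s along their line of
    centres.  Returns the maximum rigid-body rotation of either sphere
    (optimal superposition per frame), the maximum overlap volume and the
    final centre separation, which must exceed the minimum (rebound).
    """
    models = [sphere_model("coarse", solvent=0.0) for _ in range(2)]
    # The fixture is volume-normalised, so its outer vertices sit slightly
    # beyond the nominal radius; place the spheres by actual mesh extent.
    mesh_radius = np.linalg.norm(models[0].mesh.nodes, axis=1).max()
    offset = (mesh_radius + gap_nm / 2.0) * NM
    blobs = []
    for sgn, model in zip((-1.0, +1.0), models):
        x = model.reference_positions.copy()
        x[:, 0] += sgn * offset
        v = np.zeros_like(x)
        v[:, 0] = -sgn * approach_speed
        blobs.append(SimBlob(model, "langevin", lumped_mass=True,
                             positions=x, velocities=v))
    inter = InteractionSet(models, steric=True, k_steric=k_steric,
                           n_refresh=10)
    sim = Simulator(blobs, dt=dt, temperature=0.0, noise=False,
                    interactions=inter)
    n_steps = int(round(t_sim_ns * 1e-9 / dt))
    n_check = 100
    refs = [b.positions.copy() for b in blobs]
    max_rot = 0.0
    max_overlap = 0.0
    seps = []
    u_final = 0.0
    for k in range(n_steps // n_check):
        for _ in range(n_check):
            sim.step()
        for b, r0 in zip(blobs, refs):
            Rm, _ = kabsch(r0, b.positions)
            max_rot = max(max_rot, np.degrees(rotation_angle(Rm)))
        max_overlap = max(max_overlap, inter.last_overlap_volume)
        seps.append(blobs[1].centre_of_mass()[0]
                    - blobs[0].centre_of_mass()[0])
        u_final = sum(m.strain_energy(b.positions)
                      for m, b in zip(models, blobs))
    seps = np.array(seps)
    return {
        "max_rotation_deg": max_rot,
        "max_overlap_volume_nm3": max_overlap / NM**3,
        "min_separation_nm": seps.min() / NM,
        "final_separation_nm": seps[-1] / NM,
        "rebounded": bool(seps[-1] > seps.min() + 0.05 * NM),
        "final_strain_energy": u_final,
    }


def cube_pull(cube_nm: float = 4.0, gap_nm: float = 0.5,
              spring_k: float = 5.0e-5, dt: float = 1.0 * PS,
              n_steps: int = 16000, k_steric: float = 1.0e6):
    """Two cubes pulled together by springs with steric repulsion active.

    Springs connect the outer-face corner nodes of the two cubes, pulling
    them through each other (rest length zero); the test checks that the
    centres of mass approach monotonically while the overlap volume stays
    near zero.
    """
    mesh = make_cube_mesh(cube_nm, 2)
    material = DEFAULT_TEST_MATERIAL
    models = []
    blobs = []
    offset = (cube_nm + gap_nm) / 2.0 * NM
    for sgn in (-1.0, +1.0):
        drag = DragModel(solvent_viscosity=SOLVENT_VISCOSITY,
                         node_radius=0.1 * NM, temperature=TEMPERATURE)
        model = ContinuumModel(mesh, material, drag)
        x = model.reference_positions.copy()
        x[:, 0] += sgn * offset
        models.append(model)
        blobs.append(SimBlob(model, "brownian", positions=x))
    # Outer-face corner nodes (x = -a/2 of the left cube, +a/2 of the right).
    half = cube_nm / 2.0
    corners = []
    for sy in (-half, half):
        for sz in (-half, half):
            corners.append((sy, sz))
    springs = []
    nodes_nm = mesh.nodes
    for sy, sz in corners:
        left = int(np.argmin(((nodes_nm - [-half, sy, sz])**2).sum(axis=1)))
        right = int(np.argmin(((nodes_nm - [half, sy, sz])**2).sum(axis=1)))
        springs.append(Spring(0, left, 1, right, spring_k, 0.0))
    inter = InteractionSet(models, steric=True, k_steric=k_steric,
                           springs=springs, n_refresh=10)
    sim = Simulator(blobs, dt=dt, temperature=0.0, noise=False,
                    interactions=inter)
    n_check = 250
    seps = []
    overlaps = []
    for _ in range(n_steps // n_check):
        for _ in range(n_check):
            sim.step()
        seps.append(blobs[1].centre_of_mass()[0]
                    - blobs[0].centre_of_mass()[0])
        overlaps.append(inter.last_overlap_volume)
    seps = np.array(seps)
    overlaps = np.array(overlaps) / NM**3
    dsep = np.diff(seps)
    # Once the faces are in steric contact the separation equilibrates and
    # jitters at the sub-picometre level; approach is monotone above that.
    return {
        "separations_nm": seps / NM,
        "monotonic_approach": bool((dsep <= 1.0e-12).all()),
        "total_approach_nm": (seps[0] - seps[-1]) / NM,
        "max_overlap_nm3": float(overlaps.max()),
        "cube_volume_nm3": cube_nm**3,
    }


# ---------------------------------------------------------------------------
# Stiffness scaling via PCA
# ---------------------------------------------------------------------------

def stiffness_scaling(seed: int = 1, t_sim_ns: float = 20.0,
                      dt: float = 0.1 * PS, n_modes: int = 5):
    """PCA eigenvalues of two runs differing 3x in Young's modulus.

    The positional variance of every mode is proportional to k_B T / k and
    hence to 1/E, so the leading eigenvalues of the softer (E = 0.33 GPa)
    run exceed the stiffer (E = 1 GPa) run by the modulus ratio.  The mean
    of the top ``n_modes`` eigenvalue ratios estimates that factor.
    """
    ratios = {}
    eigs = {}
    for E in (0.33e9, 1.0e9):
        model = sphere_model("coarse", youngs=E)
        n_steps = int(round(t_sim_ns * 1e-9 / dt))
        blob = SimBlob(model, "brownian")
        sim = Simulator([blob], dt=dt, temperature=TEMPERATURE, seed=seed)
        traj, _ = sim.run(n_steps, n_check=250)
        frames = [f[0] * NM for f in traj.frames]      # back to metres
        eigs[E] = pca(frames, k=n_modes, fit="rigid")
    ratio = (eigs[0.33e9].eigenvalues[:n_modes]
             / eigs[1.0e9].eigenvalues[:n_modes])
    return {
        "eigenvalue_ratios": ratio,
        "mean_ratio": float(ratio.mean()),
        "expected": 1.0e9 / 0.33e9,
    }


# ---------------------------------------------------------------------------
# Fast self-test
# ---------------------------------------------------------------------------

def selftest(verbose=print):
    """Quick subset of the validation suite; returns True if all pass."""
    ok = True

    def check(name, passed, detail):
        nonlocal ok
        ok = ok and passed
        verbose(f"[{'PASS' if passed else 'FAIL'}] {name}: {detail}")

    from .meshkit import make_cube_mesh, element_volume, TetMesh
    tet = TetMesh(np.array([[0.,0,0],[1,0,0],[0,1,0],[0,0,1]]),
                  np.array([[0,1,2,3]]))
    v = element_volume(tet, 0)
    check("tet-volume", abs(v - 1/6) < 1e-12, f"V = {v:.6f}")

    res = brownian_equipartition(seed=1, t_sim_ns=1.0)
    check("equipartition-1ns",
          abs(res["deviation_last60"]) < 0.02,
          f"strain deviation {res['deviation_last60']*100:+.2f}%")

    res = stretch_test()
    check("stretch", abs(res["relative_error"]) < 0.002,
          f"E error {res['relative_error']*100:+.3f}%")

    # Bit-exact restart of a short thermal run.
    model = sphere_model("coarse")
    sim1 = Simulator([SimBlob(model, "brownian")], dt=DT_EQUIPARTITION,
                     temperature=TEMPERATURE, seed=7)
    sim1.run(400, n_check=400)
    state = sim1.checkpoint()
    sim1.run(400, n_check=400)
    model2 = sphere_model("coarse")
    sim2 = Simulator([SimBlob(model2, "brownian")], dt=DT_EQUIPARTITION,
                     temperature=TEMPERATURE, seed=7)
    sim2.run(400, n_check=400)
    sim2.restore(state)
    sim2.run(400, n_check=400)
    same = np.array_equal(sim1.blobs[0].positions, sim2.blobs[0].positions)
    check("restart", same, "bit-identical continuation")
    return ok
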