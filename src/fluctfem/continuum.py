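"""Finite-element mechanical core of a single viscoelastic body.

The body is a tetrahedral mesh with linear (constant-gradient) elements.
Its dynamics combine four ingredients, all assembled here:

* an elastic force derived from a compressible neo-Hookean strain-energy
  density ``W(F) = (G/2)(J^(-2/3) tr(F^T F) - 3) + (K/2)(J - 1)^2`` whose
  small-strain limit is exactly isotropic elasticity with shear modulus G
  and bulk modulus K;
* a Newtonian viscous stress ``sigma_v = 2 mu_s dev(d) + mu_b tr(d) I``
  (d the rate of strain), discretised into a sparse viscosity matrix;
* a local Stokes drag ``6 pi r mu_s`` per node modelling the solvent, which
  adds a diagonal block to the viscosity matrix;
* thermal forces whose covariance is ``(2 k_B T / dt) Lambda``, generated
  locally: a random symmetric stress per element for the internal part and
  an independent Gaussian kick per node for the solvent part, so that at
  equilibrium every quadratic degree of freedom carries k_B T / 2.

Positions handed to this module are in metres (node-major ``(N, 3)``
arrays); meshes are converted from nanometres once, at model construction.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .constants import K_B, NM
from .materials import DragModel, MaterialTable, Material, assign_materials

__all__ = ["ElementState", "InvertedElementError", "ContinuumModel"]


class InvertedElementError(RuntimeError):
    """An element reached non-positive volume (det F <= 0)."""


class ElementState:
    """Kinematic state of one element: F, J = det F, velocity gradient."""

    def __init__(self, deformation_gradient, velocity_gradient=None):
        self.deformation_gradient = np.asarray(deformation_gradient, dtype=float)
        self.J = float(np.linalg.det(self.deformation_gradient))
        self.velocity_gradient = velocity_gradient


def _det3(F):
    return (F[:, 0, 0] * (F[:, 1, 1] * F[:, 2, 2] - F[:, 1, 2] * F[:, 2, 1])
            - F[:, 0, 1] * (F[:, 1, 0] * F[:, 2, 2] - F[:, 1, 2] * F[:, 2, 0])
            + F[:, 0, 2] * (F[:, 1, 0] * F[:, 2, 1] - F[:, 1, 1] * F[:, 2, 0]))


def _cross_cols(F, j, k, out):
    a0, a1, a2 = F[:, 0, j], F[:, 1, j], F[:, 2, j]
    b0, b1, b2 = F[:, 0, k], F[:, 1, k], F[:, 2, k]
    out[:, 0] = a1 * b2 - a2 * b1
    out[:, 1] = a2 * b0 - a0 * b2
    out[:, 2] = a0 * b1 - a1 * b0


def _inv_transpose3(F, det):
    """Batched inverse-transpose of 3x3 matrices via the adjugate."""
    adjT = np.empty_like(F)
    _cross_cols(F, 1, 2, adjT[:, :, 0])
    _cross_cols(F, 2, 0, adjT[:, :, 1])
    _cross_cols(F, 0, 1, adjT[:, :, 2])
    adjT /= det[:, None, None]
    return adjT


class ContinuumModel:
    """Assembled mechanical model of one meshed body.

    Parameters
    ----------
    mesh : TetMesh
        Geometry in nm; converted to metres internally.
    materials : MaterialTable | Material | dict
        Per-region material parameters.
    drag : DragModel, optional
        Solvent drag and temperature; defaults to no external drag, 300 K.
    """

    def __init__(self, mesh, materials, drag: DragModel | None = None):
        if isinstance(materials, (Material, dict)):
            materials = assign_materials(mesh, materials)
        self.mesh = mesh
        self.materials = materials
        self.drag = drag if drag is not None else DragModel()

        self.elements = np.asarray(mesh.elements, dtype=np.intp)
        self.n_nodes = mesh.n_nodes
        self.reference_positions = mesh.nodes * NM          # (N, 3), metres

        x = self.reference_positions[self.elements]          # (E, 4, 3)
        edges = (x[:, 1:] - x[:, :1]).transpose(0, 2, 1)     # columns = edges
        det = _det3(edges)
        if np.any(det <= 0):
            raise InvertedElementError("mesh has non-positively oriented elements")
        self.volumes0 = det / 6.0                            # m^3
        self._edge_inv0 = np.linalg.inv(edges)
        g = np.empty((len(det), 4, 3))
        g[:, 1:, :] = self._edge_inv0
        g[:, 0, :] = -self._edge_inv0.sum(axis=1)
        self.shape_gradients0 = g                            # 1/m

        # Scatter bookkeeping: flattened node index per (element, vertex).
        self._scatter_idx = self.elements.ravel()
        self._scatter_idx3 = (
            3 * self.elements[:, :, None] + np.arange(3)[None, None, :]
        ).ravel()

        mt = materials
        self._G = mt.shear_modulus
        self._K = mt.bulk_modulus
        self._mu_s = mt.shear_viscosity
        self._mu_b = mt.bulk_viscosity
        self._rho = mt.density

        # Per-node Stokes drag (kg/s), uniform by default.
        self.node_drag = np.full(self.n_nodes, self.drag.node_drag)

        # Noise amplitudes are precomputed lazily per (T, dt) pair.
        self._noise_cache = None

    # ------------------------------------------------------------------
    # Kinematics
    # ------------------------------------------------------------------

    def deformation_gradients(self, positions: np.ndarray) -> np.ndarray:
        """F for every element; maps reference edges to current edges."""
        x = positions[self.elements]
        edges = (x[:, 1:] - x[:, :1]).transpose(0, 2, 1)
        return edges @ self._edge_inv0

    def deformation_gradient(self, positions: np.ndarray, e: int) -> ElementState:
        F = self.deformation_gradients(positions)[e]
        state = ElementState(F)
        if state.J <= 0:
            raise InvertedElementError(f"element {e} is inverted (J = {state.J:g})")
        return state

    # ------------------------------------------------------------------
    # Elasticity
    # ------------------------------------------------------------------

    def _piola_stress(self, F):
        J = _det3(F)
        if np.any(J <= 0.0):
            bad = int(np.flatnonzero(J <= 0.0)[0])
            raise InvertedElementError(
                f"element {bad} inverted (J = {J[bad]:.3g})"
            )
        FinvT = _inv_transpose3(F, J)
        I1 = (F * F).sum(axis=(1, 2))
        Jm23 = J ** (-2.0 / 3.0)
        P = (self._G * Jm23)[:, None, None] * (
            F - (I1 / 3.0)[:, None, None] * FinvT
        ) + (self._K * (J - 1.0) * J)[:, None, None] * FinvT
        return P, J, I1, Jm23

    def _scatter_stress(self, PV: np.ndarray) -> np.ndarray:
        """Map per-element stress*volume to nodal forces f_a = -PV grad N_a."""
        f = np.matmul(self.shape_gradients0, PV.transpose(0, 2, 1))
        out = np.bincount(self._scatter_idx3, weights=f.ravel(),
                          minlength=3 * self.n_nodes)
        return -out.reshape(self.n_nodes, 3)

    def elastic_forces(self, positions: np.ndarray) -> np.ndarray:
        """Nodal elastic forces E_p = -dU/dx (N, 3), newtons."""
        F = self.deformation_gradients(positions)
        P, _, _, _ = self._piola_stress(F)
        return self._scatter_stress(P * self.volumes0[:, None, None])

    def strain_energy(self, positions: np.ndarray) -> float:
        """Total strain energy U (J); zero at the reference configuration."""
        F = self.deformation_gradients(positions)
        J = _det3(F)
        if np.any(J <= 0.0):
            raise InvertedElementError("inverted element in strain_energy")
        I1 = (F * F).sum(axis=(1, 2))
        W = (0.5 * self._G * (J ** (-2.0 / 3.0) * I1 - 3.0)
             + 0.5 * self._K * (J - 1.0) ** 2)
        return float(np.dot(self.volumes0, W))

    def _scatter(self, per_vertex: np.ndarray) -> np.ndarray:
        flat = per_vertex.reshape(-1, 3)
        out = np.empty((self.n_nodes, 3))
        for c in range(3):
            out[:, c] = np.bincount(
                self._scatter_idx, weights=flat[:, c], minlength=self.n_nodes
            )
        return out

    # ------------------------------------------------------------------
    # System matrices
    # ------------------------------------------------------------------

    def _assemble_isotropic_operator(self, shear, bulk, positions=None):
        """Sparse 3N x 3N operator of the isotropic tensor c1*dev + c2*vol.

        With (shear, bulk) = (G, K) this is the small-strain stiffness K_pq;
        with the viscosities it is the internal viscosity matrix.  Blocks:
        ``V [ s ((g_a.g_b) I + g_b g_a^T) + (b - 2s/3) g_a g_b^T ]``.
        """
        if positions is None:
            V, g = self.volumes0, self.shape_gradients0
        else:
            x = positions[self.elements]
            edges = (x[:, 1:] - x[:, :1]).transpose(0, 2, 1)
            det = _det3(edges)
            if np.any(det <= 0):
                raise InvertedElementError("inverted element in operator assembly")
            V = det / 6.0
            inv = np.linalg.inv(edges)
            g = np.empty_like(self.shape_gradients0)
            g[:, 1:, :] = inv
            g[:, 0, :] = -inv.sum(axis=1)

        c2 = bulk - 2.0 * shear / 3.0
        gdot = np.einsum("eai,ebi->eab", g, g)
        eye = np.eye(3)
        blocks = (
            shear[:, None, None, None, None]
            * (gdot[:, :, :, None, None] * eye
               + np.einsum("ebi,eaj->eabij", g, g))
            + c2[:, None, None, None, None] * np.einsum("eai,ebj->eabij", g, g)
        )
        blocks *= V[:, None, None, None, None]

        el = self.elements
        rows = (3 * el[:, :, None, None, None]
                + np.arange(3)[None, None, None, :, None])
        rows = np.broadcast_to(rows, blocks.shape)
        cols = (3 * el[:, None, :, None, None]
                + np.arange(3)[None, None, None, None, :])
        cols = np.broadcast_to(cols, blocks.shape)
        n = 3 * self.n_nodes
        A = sp.coo_matrix(
            (blocks.ravel(), (rows.ravel(), cols.ravel())), shape=(n, n)
        )
        return A.tocsr()

    def mass_matrix(self, lumped: bool = False) -> sp.csr_matrix:
        """Mass matrix (kg).  Consistent by default; lumped puts rho V/4
        on each vertex.  Row sums reproduce the total mass."""
        m = self._rho * self.volumes0
        n = 3 * self.n_nodes
        if lumped:
            diag = np.zeros(self.n_nodes)
            np.add.at(diag, self._scatter_idx, np.repeat(m / 4.0, 4))
            return sp.diags(np.repeat(diag, 3)).tocsr()
        blocks = np.tile((m / 20.0)[:, None, None, None, None] * np.eye(3),
                         (1, 4, 4, 1, 1)).copy()
        for a in range(4):
            blocks[:, a, a] *= 2.0
        el = self.elements
        rows = np.broadcast_to(
            3 * el[:, :, None, None, None] + np.arange(3)[None, None, None, :, None],
            blocks.shape)
        cols = np.broadcast_to(
            3 * el[:, None, :, None, None] + np.arange(3)[None, None, None, None, :],
            blocks.shape)
        return sp.coo_matrix(
            (blocks.ravel(), (rows.ravel(), cols.ravel())), shape=(n, n)
        ).tocsr()

    def stiffness_matrix(self) -> sp.csr_matrix:
        """Small-strain stiffness K_pq = -dE_p/dx_q at the reference."""
        return self._assemble_isotropic_operator(self._G, self._K)

    def viscosity_matrix(self, positions=None) -> sp.csr_matrix:
        """Viscosity matrix Lambda = Lambda_internal + diagonal Stokes drag.

        By default the internal part is assembled on the reference geometry
        (the thermal forces are generated against the same operator); pass
        current positions to evaluate it on a deformed configuration.
        """
        lam = self._assemble_isotropic_operator(
            self._mu_s, self._mu_b, positions=positions
        )
        if np.any(self.node_drag > 0):
            lam = lam + sp.diags(np.repeat(self.node_drag, 3))
        return lam.tocsr()

    # ------------------------------------------------------------------
    # Thermal forces
    # ------------------------------------------------------------------

    def _noise_amplitudes(self, T, dt):
        key = (T, dt)
        if self._noise_cache is not None and self._noise_cache[0] == key:
            return self._noise_cache[1]
        kappa = 2.0 * K_B * T / (self.volumes0 * dt)         # stress variance scale
        amp_shear = np.sqrt(kappa * self._mu_s)
        amp_bulk = np.sqrt(kappa * self._mu_b)
        amp_node = np.sqrt(2.0 * K_B * T * self.node_drag / dt)
        self._noise_cache = (key, (amp_shear, amp_bulk, amp_node))
        return self._noise_cache[1]

    def thermal_forces(self, T: float, dt: float, rng: np.random.Generator
                       ) -> np.ndarray:
        """Stochastic force N_p with covariance (2 k_B T / dt) Lambda.

        The internal contribution draws one random symmetric stress per
        element (deviatoric and volumetric parts coupled to the shear and
        bulk viscosities respectively) and maps it to the nodes through the
        same operator as the viscous stress, so it is strictly local and
        exerts zero net force and torque per element.  The solvent
        contribution is an independent Gaussian kick per node against the
        diagonal drag.
        """
        if dt <= 0.0:
            raise ValueError("dt must be positive")
        if T == 0.0:
            return np.zeros((self.n_nodes, 3))
        piV = self._thermal_stress_volume(T, dt, rng)
        forces = self._scatter_stress(piV)
        amp_node = self._noise_amplitudes(T, dt)[2]
        if np.any(amp_node > 0):
            forces += amp_node[:, None] * rng.standard_normal((self.n_nodes, 3))
        return forces

    def _thermal_stress_volume(self, T, dt, rng) -> np.ndarray:
        """Random symmetric stress per element, premultiplied by V_e.

        Drawn so that the nodal forces -V pi grad(N) have the covariance of
        the internal viscous dissipation: deviatoric part coupled to mu_s,
        isotropic part to mu_b.  A symmetric Gaussian matrix S with diagonal
        variance 2 and off-diagonal variance 1 is projected onto its
        deviator; an independent scalar carries the volumetric channel.
        """
        amp_shear, amp_bulk, _ = self._noise_amplitudes(T, dt)
        E = len(self.volumes0)
        d = rng.standard_normal((E, 6))
        xi = rng.standard_normal(E)
        sq2 = np.sqrt(2.0)
        tr3 = sq2 * (d[:, 0] + d[:, 1] + d[:, 2]) / 3.0
        pi = np.empty((E, 3, 3))
        iso = amp_bulk * xi
        for i in range(3):
            pi[:, i, i] = amp_shear * (sq2 * d[:, i] - tr3) + iso
        pi[:, 0, 1] = pi[:, 1, 0] = amp_shear * d[:, 3]
        pi[:, 0, 2] = pi[:, 2, 0] = amp_shear * d[:, 4]
        pi[:, 1, 2] = pi[:, 2, 1] = amp_shear * d[:, 5]
        pi *= self.volumes0[:, None, None]
        return pi

    def nodal_forces(self, positions, T=0.0, dt=None, rng=None) -> np.ndarray:
        """Elastic plus (optionally) thermal nodal forces, fused.

        Equivalent to ``elastic_forces(x) + thermal_forces(T, dt, rng)`` but
        with a single stress-to-node scatter; this is the integrator's hot
        path.
        """
        F = self.deformation_gradients(positions)
        P, _, _, _ = self._piola_stress(F)
        PV = P * self.volumes0[:, None, None]
        if T > 0.0 and rng is not None:
            PV += self._thermal_stress_volume(T, dt, rng)
            forces = self._scatter_stress(PV)
            amp_node = self._noise_amplitudes(T, dt)[2]
            if np.any(amp_node > 0):
                forces += amp_node[:, None] * rng.standard_normal(
                    (self.n_nodes, 3))
            return forces
        return self._scatter_stress(PV)

    # ------------------------------------------------------------------
    # Convenience
    # ------------------------------------------------------------------

    def total_mass(self) -> float:
        return float(np.dot(self._rho, self.volumes0))

    def kinetic_energy(self, velocities: np.ndarray, M=None) -> float:
        if M is None:
            M = self.mass_matrix()
        v = velocities.ravel()
        return 0.5 * float(v @ (M @ v))
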