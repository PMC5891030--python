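"""Linear elastic model: linearised stiffness, normal modes, time-scales.

A linear expansion of the elastic force about the reference configuration
gives a stiffness matrix K; its (generalised) eigenvectors are the normal
modes of the body, with six zero-eigenvalue rigid modes for a free blob.
Combining K and the mass matrix with the viscosity matrix yields two
relaxation spectra: the viscoelastic one (K v = (1/tau) Lambda v), whose
slow end bounds the simulated time needed to sample the softest mode, and
the inertial one (Lambda v = (1/tau) M v), whose fast end bounds a stable
explicit time-step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .constants import NM
from .trajectory import Trajectory

__all__ = ["EigenSystem", "stiffness_matrix", "normal_modes", "timescales",
           "animate_mode", "rigid_mode_count"]

_DENSE_LIMIT = 1500


@dataclass
class EigenSystem:
    """Eigenvalues (ascending) and column eigenvectors of a 3N operator."""

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    metadata: dict = field(default_factory=dict)

    @property
    def k(self) -> int:
        return len(self.eigenvalues)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            for key, v in self.metadata.items():
                fh.write(f"# {key}: {v}\n")
            fh.write("eigenvalue\tcomponents...\n")
            for lam, vec in zip(self.eigenvalues, self.eigenvectors.T):
                fh.write("\t".join([f"{lam:.10e}"] +
                                   [f"{c:.10e}" for c in vec]) + "\n")


def stiffness_matrix(model) -> sp.csr_matrix:
    """K_pq = -dE_p/dx_q at the reference configuration.

    Assembled analytically from the linearised constitutive model; the
    result is symmetric positive-semidefinite with exactly six rigid-body
    null modes for an unconstrained body.
    """
    K = model.stiffness_matrix()
    asym = abs(K - K.T).max()
    if asym > 1.0e-6 * max(abs(K).max(), 1e-300):
        raise RuntimeError(
            "stiffness matrix asymmetric: broken elastic force linearisation"
        )
    return K


def normal_modes(K, M=None, k=None) -> EigenSystem:
    """Eigenpairs of K (optionally generalised with mass matrix M).

    Eigenvalues ascend; eigenvectors are M-orthonormal (or orthonormal for
    the standard problem).  ``k`` limits the number of pairs returned.
    """
    n = K.shape[0]
    if k is None:
        k = n
    if k > n:
        raise ValueError("cannot request more modes than degrees of freedom")
    dense = n <= _DENSE_LIMIT
    if dense:
        Kd = K.toarray() if sp.issparse(K) else np.asarray(K)
        Md = None if M is None else (M.toarray() if sp.issparse(M)
                                     else np.asarray(M))
        vals, vecs = sla.eigh(Kd, Md)
        vals, vecs = vals[:k], vecs[:, :k]
    else:
        sigma = -abs(K.diagonal()).max() * 1.0e-8
        vals, vecs = spla.eigsh(K, k=k, M=M, sigma=sigma, which="LM")
        order = np.argsort(vals)
        vals, vecs = vals[order], vecs[:, order]
    return EigenSystem(vals, vecs,
                       metadata={"operator": "stiffness",
                                 "generalised": M is not None})


def rigid_mode_count(eig: EigenSystem, rel_tol: float = 1.0e-8) -> int:
    """Number of (numerically) zero eigenvalues at the soft end."""
    scale = max(abs(eig.eigenvalues).max(), 1e-300)
    return int(np.sum(np.abs(eig.eigenvalues) < rel_tol * scale))


def timescales(M, K, Lam):
    """Two relaxation spectra (seconds, ascending).

    Returns ``(viscoelastic, inertial)``: the viscoelastic times solve
    K v = (1/tau) Lambda v restricted to non-rigid modes (the slowest
    bounds the total simulation length needed); the inertial times solve
    Lambda v = (1/tau) M v (the fastest bounds the stable time-step).
    """
    Kd = K.toarray() if sp.issparse(K) else np.asarray(K)
    Ld = Lam.toarray() if sp.issparse(Lam) else np.asarray(Lam)
    Md = M.toarray() if sp.issparse(M) else np.asarray(M)
    lam_scale = abs(Ld).max()
    if lam_scale == 0:
        raise ValueError("singular viscosity matrix")
    rates_ve = sla.eigh(Kd, Ld, eigvals_only=True)
    scale = max(rates_ve.max(), 0.0)
    rates_ve = rates_ve[rates_ve > 1.0e-8 * scale]     # drop rigid modes
    tau_ve = np.sort(1.0 / rates_ve)
    rates_in = sla.eigh(Ld, Md, eigvals_only=True)
    rates_in = rates_in[rates_in > 0]
    tau_in = np.sort(1.0 / rates_in)
    return tau_ve, tau_in


def animate_mode(reference_positions, eig: EigenSystem, mode: int,
                 amplitude: float, n_frames: int = 20) -> Trajectory:
    """Sinusoidal sweep x(phi) = x0 + A sin(phi) v_mode as a trajectory.

    ``amplitude`` is in metres; the trajectory is written in nm.  Animating
    a rigid mode is allowed (with a warning by the caller if desired).
    """
    if not 0 <= mode < eig.k:
        raise IndexError(f"mode {mode} out of range")
    x0 = np.asarray(reference_positions, dtype=float)
    v = eig.eigenvectors[:, mode].reshape(-1, 3)
    traj = Trajectory(meta={"mode": mode, "amplitude_m": amplitude})
    for i in range(n_frames):
        phi = 2.0 * np.pi * i / n_frames
        x = x0 + amplitude * np.sin(phi) * v
        traj.append(float(i), [x / NM])
    return traj
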