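"""Trajectory post-processing: energy statistics, RMSD, diffusion, PCA.

Operates on in-memory :class:`~fluctfem.trajectory.Trajectory` /
:class:`~fluctfem.trajectory.Measurements` objects or plain coordinate
arrays.  RMSD optionally removes rigid-body motion with a Kabsch fit; PCA
diagonalises the covariance of the (optionally fitted) node coordinates,
and eigensystems are compared through their inner-product matrix and the
normalised eigenspace overlap (1/n) sum_{i,j<=n} (v_i . w_j)^2.
"""

from __future__ import annotations

import warnings

import numpy as np

from .constants import K_B
from .lem import EigenSystem

__all__ = [
    "energy_convergence", "kabsch", "rmsd", "msd_per_step",
    "diffusion_check", "pca", "compare_eigensystems",
]


def energy_convergence(times, energies, temperature, n_dof,
                       tail: int = 60):
    """Running mean of an energy series against its equipartition value.

    Returns a dict with the running mean ``<U(t)>``, the mean over the last
    ``tail`` recorded frames and its relative deviation from
    ``n_dof * k_B T / 2``.  With fewer than ``tail`` frames the mean is
    taken over all frames (with a warning).
    """
    u = np.asarray(energies, dtype=float)
    t = np.asarray(times, dtype=float)
    if len(u) == 0:
        raise ValueError("empty energy series")
    if len(u) < tail:
        warnings.warn(f"only {len(u)} frames; tail average uses all of them")
        tail = len(u)
    running = np.cumsum(u) / np.arange(1, len(u) + 1)
    theory = n_dof * K_B * temperature / 2.0
    tail_mean = u[-tail:].mean()
    return {
        "times": t,
        "running_mean": running,
        "tail_mean": tail_mean,
        "theory": theory,
        "relative_deviation": tail_mean / theory - 1.0,
    }


def kabsch(P, Q, weights=None):
    """Optimal rotation R and translation t with R@P_c ~ Q_c (least squares).

    Returns ``(R, t)`` such that ``P @ R.T + t`` best superimposes P onto Q.
    """
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    w = (np.ones(len(P)) if weights is None
         else np.asarray(weights, float))
    w = w / w.sum()
    pc = (w[:, None] * P).sum(axis=0)
    qc = (w[:, None] * Q).sum(axis=0)
    H = (w[:, None] * (P - pc)).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    return R, t


def rotation_angle(R) -> float:
    """Rotation angle (radians) of a proper rotation matrix."""
    c = (np.trace(R) - 1.0) / 2.0
    return float(np.arccos(np.clip(c, -1.0, 1.0)))


def rmsd(frames, reference, fit: str = "none", weights=None) -> np.ndarray:
    """Root-mean-square nodal deviation per frame.

    ``fit='rigid'`` removes the optimal rotation+translation (Kabsch)
    before measuring; ``fit='none'`` keeps diffusional motion in the trace.
    """
    if fit not in ("none", "rigid"):
        raise ValueError("fit must be 'none' or 'rigid'")
    ref = np.asarray(reference, float)
    out = np.empty(len(frames))
    for k, fr in enumerate(frames):
        fr = np.asarray(fr, float)
        if fr.shape != ref.shape:
            raise ValueError("frame/reference node count mismatch")
        if fit == "rigid":
            R, t = kabsch(fr, ref, weights)
            fr = fr @ R.T + t
        out[k] = np.sqrt(((fr - ref) ** 2).sum(axis=1).mean())
    return out


def msd_per_step(centroids) -> float:
    """Mean of |r(t+dt) - r(t)|^2 over all consecutive step pairs."""
    c = np.asarray(centroids, float)
    if len(c) < 2:
        raise ValueError("need at least two samples")
    d = np.diff(c, axis=0)
    return float((d ** 2).sum(axis=1).mean())


def diffusion_check(centroids, dt, temperature, *, drag=None, mass=None):
    """Relative error of the per-step centroid MSD against theory.

    For the overdamped scheme pass ``drag`` (total object drag, kg/s):
    theory is 6 k_B T dt / drag.  For the inertial scheme pass ``mass``
    (total mass, kg): in the ballistic regime theory is 3 k_B T dt^2 / m.
    """
    msd = msd_per_step(centroids)
    kBT = K_B * temperature
    if (drag is None) == (mass is None):
        raise ValueError("pass exactly one of drag= or mass=")
    theory = (6.0 * kBT * dt / drag if drag is not None
              else 3.0 * kBT * dt ** 2 / mass)
    return {"msd": msd, "theory": theory,
            "relative_error": msd / theory - 1.0}


def pca(frames, k=None, fit: str = "rigid", weights=None) -> EigenSystem:
    """PCA of node coordinates: covariance eigendecomposition.

    Frames are optionally rigid-fitted to their mean structure (iterated
    once), then mean-centred; eigenvalues are returned in descending
    variance order, eigenvectors as orthonormal columns.  ``k`` beyond the
    covariance rank is truncated with a warning.
    """
    X = np.stack([np.asarray(f, float) for f in frames])   # (F, N, 3)
    F, N, _ = X.shape
    if F < 2:
        raise ValueError("PCA needs at least two frames")
    if fit == "rigid":
        ref = X.mean(axis=0)
        for _ in range(2):
            for i in range(F):
                R, t = kabsch(X[i], ref, weights)
                X[i] = X[i] @ R.T + t
            ref = X.mean(axis=0)
    flat = X.reshape(F, 3 * N)
    flat -= flat.mean(axis=0)
    rank = min(F - 1, 3 * N)
    if k is None:
        k = rank
    if k > rank:
        warnings.warn(f"requested {k} components but rank is {rank}; "
                      "truncating")
        k = rank
    # Economy SVD of the centred frame matrix.
    _, s, Vt = np.linalg.svd(flat, full_matrices=False)
    var = s ** 2 / (F - 1)
    return EigenSystem(var[:k], Vt[:k].T,
                       metadata={"operator": "pca", "n_frames": F,
                                 "fit": fit, "descending": True})


def compare_eigensystems(a: EigenSystem, b: EigenSystem, n: int):
    """Inner-product matrix |v_i . w_j| and eigenspace overlap.

    The overlap is (1/n) sum_{i<=n} sum_{j<=n} (v_i . w_j)^2; it is 1 when
    the leading n-subspaces coincide and 0 when they are orthogonal.
    """
    if n > a.k or n > b.k:
        raise ValueError("n exceeds the available number of modes")
    V = a.eigenvectors[:, :n]
    W = b.eigenvectors[:, :n]
    inner = V.T @ W
    overlap = float((inner ** 2).sum() / n)
    return np.abs(inner), overlap
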