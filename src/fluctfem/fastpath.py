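"""Compiled inner loops for single-body thermal simulations.

The generic :class:`~fluctfem.integrators.Simulator` step is vectorised
numpy; for the long equipartition and diffusion protocols (10^5 - 10^6
steps of one body with no inter-body interactions) a numba-compiled kernel
advances whole blocks of steps at once.  The kernels consume Gaussian
draws produced by the *same* generator calls, in the same order, as the
numpy path, so trajectories agree between paths up to floating-point
associativity and restarts remain reproducible.

If numba is unavailable the simulator transparently falls back to the
numpy step loop.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is expected to be present
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if len(args) == 1 and callable(args[0]):
            return args[0]

        def deco(f):
            return f

        return deco

__all__ = ["HAVE_NUMBA", "FastRunner"]


@njit(cache=True)
def _element_forces(x, el, g0, GV, KV, asv, abv, nd, nxi, add_noise, f):
    """Accumulate -(P + pi) V grad(N) into the flat force vector f.

    Returns the index of the first inverted element, or -1.
    """
    E = el.shape[0]
    sq2 = np.sqrt(2.0)
    for e in range(E):
        F00 = 0.0; F01 = 0.0; F02 = 0.0
        F10 = 0.0; F11 = 0.0; F12 = 0.0
        F20 = 0.0; F21 = 0.0; F22 = 0.0
        for a in range(4):
            n3 = 3 * el[e, a]
            x0 = x[n3]; x1 = x[n3 + 1]; x2 = x[n3 + 2]
            ga0 = g0[e, a, 0]; ga1 = g0[e, a, 1]; ga2 = g0[e, a, 2]
            F00 += x0 * ga0; F01 += x0 * ga1; F02 += x0 * ga2
            F10 += x1 * ga0; F11 += x1 * ga1; F12 += x1 * ga2
            F20 += x2 * ga0; F21 += x2 * ga1; F22 += x2 * ga2
        c00 = F11 * F22 - F12 * F21
        c01 = F12 * F20 - F10 * F22
        c02 = F10 * F21 - F11 * F20
        J = F00 * c00 + F01 * c01 + F02 * c02
        if J <= 0.0:
            return e
        c10 = F02 * F21 - F01 * F22
        c11 = F00 * F22 - F02 * F20
        c12 = F01 * F20 - F00 * F21
        c20 = F01 * F12 - F02 * F11
        c21 = F02 * F10 - F00 * F12
        c22 = F00 * F11 - F01 * F10
        I1 = (F00 * F00 + F01 * F01 + F02 * F02
              + F10 * F10 + F11 * F11 + F12 * F12
              + F20 * F20 + F21 * F21 + F22 * F22)
        c1 = GV[e] * J ** (-2.0 / 3.0)
        cc = (KV[e] * (J - 1.0) * J - c1 * I1 / 3.0) / J
        P00 = c1 * F00 + cc * c00; P01 = c1 * F01 + cc * c01
        P02 = c1 * F02 + cc * c02
        P10 = c1 * F10 + cc * c10; P11 = c1 * F11 + cc * c11
        P12 = c1 * F12 + cc * c12
        P20 = c1 * F20 + cc * c20; P21 = c1 * F21 + cc * c21
        P22 = c1 * F22 + cc * c22
        if add_noise:
            d0 = nd[e, 0]; d1 = nd[e, 1]; d2 = nd[e, 2]
            tr3 = sq2 * (d0 + d1 + d2) / 3.0
            iso = abv[e] * nxi[e]
            P00 += asv[e] * (sq2 * d0 - tr3) + iso
            P11 += asv[e] * (sq2 * d1 - tr3) + iso
            P22 += asv[e] * (sq2 * d2 - tr3) + iso
            s01 = asv[e] * nd[e, 3]; s02 = asv[e] * nd[e, 4]
            s12 = asv[e] * nd[e, 5]
            P01 += s01; P10 += s01
            P02 += s02; P20 += s02
            P12 += s12; P21 += s12
        for a in range(4):
            n3 = 3 * el[e, a]
            ga0 = g0[e, a, 0]; ga1 = g0[e, a, 1]; ga2 = g0[e, a, 2]
            f[n3] -= P00 * ga0 + P01 * ga1 + P02 * ga2
            f[n3 + 1] -= P10 * ga0 + P11 * ga1 + P12 * ga2
            f[n3 + 2] -= P20 * ga0 + P21 * ga1 + P22 * ga2
    return -1


@njit(cache=True)
def _record_com(x, w, com_out, s):
    cx = 0.0; cy = 0.0; cz = 0.0
    for n in range(w.shape[0]):
        cx += w[n] * x[3 * n]
        cy += w[n] * x[3 * n + 1]
        cz += w[n] * x[3 * n + 2]
    com_out[s, 0] = cx; com_out[s, 1] = cy; com_out[s, 2] = cz


@njit(cache=True)
def _brownian_chunk(x, el, g0, GV, KV, asv, abv, nd, nxi, nn,
                    inv_op, free, dt, w, com_out, use_noise, n_steps):
    f = np.empty(x.shape[0])
    for s in range(n_steps):
        f[:] = 0.0
        si = s if use_noise else 0
        bad = _element_forces(x, el, g0, GV, KV, asv, abv,
                              nd[si], nxi[si], use_noise, f)
        if bad >= 0:
            return bad
        if use_noise:
            f += nn[s]
        v = np.dot(inv_op, f[free])
        for i in range(free.shape[0]):
            x[free[i]] += dt * v[i]
        if com_out.shape[0] > 0:
            _record_com(x, w, com_out, s)
    return -1


@njit(cache=True)
def _langevin_chunk(x, v, el, g0, GV, KV, asv, abv, nd, nxi, nn,
                    inv_op, lam, free, dt, w, com_out, use_noise, n_steps):
    f = np.empty(x.shape[0])
    for s in range(n_steps):
        f[:] = 0.0
        si = s if use_noise else 0
        bad = _element_forces(x, el, g0, GV, KV, asv, abv,
                              nd[si], nxi[si], use_noise, f)
        if bad >= 0:
            return bad
        if use_noise:
            f += nn[s]
        f -= np.dot(lam, v)
        acc = np.dot(inv_op, f[free])
        for i in range(free.shape[0]):
            v[free[i]] += dt * acc[i]
            x[free[i]] += dt * v[free[i]]
        if com_out.shape[0] > 0:
            _record_com(x, w, com_out, s)
    return -1


class FastRunner:
    """Drives the compiled kernels for a single-blob simulator."""

    def __init__(self, sim, tracker=None):
        blob = sim.blobs[0]
        model = blob.model
        self.sim = sim
        self.blob = blob
        self.model = model
        self.tracker = tracker
        self.dt = sim.dt
        E = len(model.volumes0)
        self.el = np.ascontiguousarray(model.elements, dtype=np.int64)
        self.g0 = np.ascontiguousarray(model.shape_gradients0)
        self.GV = model._G * model.volumes0
        self.KV = model._K * model.volumes0
        if sim.noise:
            amp_s, amp_b, amp_n = model._noise_amplitudes(
                sim.temperature, sim.dt)
            self.asv = amp_s * model.volumes0
            self.abv = amp_b * model.volumes0
            self.ampn = np.repeat(amp_n, 3)
            self.has_node_noise = bool(np.any(amp_n > 0))
        else:
            self.asv = np.zeros(E)
            self.abv = np.zeros(E)
            self.ampn = np.zeros(3 * model.n_nodes)
            self.has_node_noise = False
        self.inv_op = np.ascontiguousarray(blob._solver._inv)
        self.free = blob.free_dofs.astype(np.int64)
        self.lam = (np.ascontiguousarray(blob._lambda)
                    if blob.scheme == "langevin"
                    else np.zeros((1, 1)))
        self.w = (np.ascontiguousarray(tracker.weights)
                  if tracker is not None else np.zeros(model.n_nodes))
        self._dummy_nd = np.zeros((1, E, 6))
        self._dummy_nxi = np.zeros((1, E))

    def advance(self, n_steps: int, chunk: int = 512) -> None:
        sim, blob = self.sim, self.blob
        rng = sim.rngs[0]
        E = len(self.model.volumes0)
        N = self.model.n_nodes
        x = blob.positions.reshape(-1)
        v = blob.velocities.reshape(-1)
        done = 0
        while done < n_steps:
            m = min(chunk, n_steps - done)
            if sim.noise:
                nd = np.empty((m, E, 6))
                nxi = np.empty((m, E))
                nn = np.zeros((m, 3 * N))
                # One generator call per step, mirroring the numpy path's
                # draw order exactly.
                for s in range(m):
                    nd[s] = rng.standard_normal((E, 6))
                    nxi[s] = rng.standard_normal(E)
                    if self.has_node_noise:
                        nn[s] = self.ampn * rng.standard_normal(3 * N)
            else:
                nd, nxi = self._dummy_nd, self._dummy_nxi
                nn = np.zeros((1, 3 * N))
            com = (np.empty((m, 3)) if self.tracker is not None
                   else np.empty((0, 3)))
            if blob.scheme == "brownian":
                bad = _brownian_chunk(
                    x, self.el, self.g0, self.GV, self.KV,
                    self.asv, self.abv, nd, nxi, nn,
                    self.inv_op, self.free, self.dt, self.w, com,
                    sim.noise, m,
                )
            else:
                bad = _langevin_chunk(
                    x, v, self.el, self.g0, self.GV, self.KV,
                    self.asv, self.abv, nd, nxi, nn,
                    self.inv_op, self.lam, self.free, self.dt, self.w,
                    com, sim.noise, m,
                )
            if bad >= 0:
                from .continuum import InvertedElementError

                raise InvertedElementError(
                    f"element {bad} inverted near step {sim.step_index + done}"
                )
            if self.tracker is not None and com.shape[0]:
                self.tracker.extend(com)
            done += m
        sim.step_index += n_steps
        sim.time = sim.step_index * sim.dt
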