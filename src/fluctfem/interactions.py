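"""Inter-body forces: steric overlap repulsion, surface Lennard-Jones,
Hookean springs and precomputed bead potentials.

Steric repulsion gives overlapping surface tetrahedra an energy
``k_steric * V_overlap``; the force is the numerical gradient of the
intersection volume with respect to rigid relative displacement, applied at
the overlap centroid and spread onto the elements' nodes by barycentric
weights.  The Lennard-Jones term is a double surface integral of a
force-per-area-squared kernel over face pairs, approximated by fixed-order
triangle quadrature.  Candidate face pairs come from a linked-cell voxel
grid refreshed every ``n_refresh`` steps, keeping the search linear in the
number of surface faces.

All geometry in this module is in metres (simulation frame).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LJParamMatrix", "Spring", "BeadSet", "VoxelGrid",
    "tet_intersection_volume", "tet_intersection_volume_centroid",
    "candidate_face_pairs", "steric_forces", "lj_face_forces",
    "spring_forces", "bead_forces", "InteractionSet",
    "N_FACE_TYPES",
]

# Number of face interaction types; t = -1 marks an inactive face.
N_FACE_TYPES = 7


# ---------------------------------------------------------------------------
# Convex clipping: intersection volume of two tetrahedra
# ---------------------------------------------------------------------------

def _clip_polygon(poly, n, d, eps):
    """Clip an ordered polygon against half-space n.x <= d.

    Vertices are plain (x, y, z) tuples; pure scalar arithmetic keeps the
    per-pair cost low in the collision loop.
    """
    out = []
    cut = []
    m = len(poly)
    nx, ny, nz = n
    dist = [nx * p[0] + ny * p[1] + nz * p[2] - d for p in poly]
    for i in range(m):
        j = i + 1 if i + 1 < m else 0
        pi, pj = poly[i], poly[j]
        di, dj = dist[i], dist[j]
        if di <= eps:
            out.append(pi)
            if di < -eps and dj > eps:
                t = di / (di - dj)
                q = (pi[0] + t * (pj[0] - pi[0]),
                     pi[1] + t * (pj[1] - pi[1]),
                     pi[2] + t * (pj[2] - pi[2]))
                out.append(q)
                cut.append(q)
            elif -eps <= di <= eps:
                cut.append(pi)
        elif dj < -eps:
            t = di / (di - dj)
            q = (pi[0] + t * (pj[0] - pi[0]),
                 pi[1] + t * (pj[1] - pi[1]),
                 pi[2] + t * (pj[2] - pi[2]))
            out.append(q)
            cut.append(q)
    return out, cut


def _polyhedron_volume_centroid(faces):
    """Volume and centroid from outward-oriented faces (divergence theorem)."""
    vol = 0.0
    cx = cy = cz = 0.0
    for poly in faces:
        if len(poly) < 3:
            continue
        p0 = poly[0]
        for i in range(1, len(poly) - 1):
            a, b = poly[i], poly[i + 1]
            crx = a[1] * b[2] - a[2] * b[1]
            cry = a[2] * b[0] - a[0] * b[2]
            crz = a[0] * b[1] - a[1] * b[0]
            v6 = p0[0] * crx + p0[1] * cry + p0[2] * crz
            vol += v6
            cx += v6 * (p0[0] + a[0] + b[0])
            cy += v6 * (p0[1] + a[1] + b[1])
            cz += v6 * (p0[2] + a[2] + b[2])
    vol /= 6.0
    if vol > 0:
        s = 1.0 / (24.0 * vol)
        return vol, np.array([cx * s, cy * s, cz * s])
    return vol, np.zeros(3)


def _cross3(a, b):
    return (a[1] * b[2] - a[2] * b[1],
            a[2] * b[0] - a[0] * b[2],
            a[0] * b[1] - a[1] * b[0])


def _tet_faces(tet):
    # Outward-wound faces of a positively oriented tetrahedron.
    idx = [(1, 2, 3), (0, 3, 2), (0, 1, 3), (0, 2, 1)]
    pts = [tuple(p) for p in tet]
    return [[pts[i] for i in f] for f in idx]


def _ensure_positive(tet):
    d = tet[1:] - tet[0]
    c = _cross3(d[1], d[2])
    if d[0, 0] * c[0] + d[0, 1] * c[1] + d[0, 2] * c[2] < 0:
        tet = tet[[0, 1, 3, 2]]
    return tet


def tet_intersection_volume_centroid(tetA, tetB):
    """Exact intersection volume (m^3) and centroid of two tetrahedra.

    Computed by successively clipping A against the four face half-spaces
    of B (Sutherland-Hodgman in 3D); the intersection of convex bodies is
    convex, so each cut cap is a convex polygon.  Degenerate input returns
    zero volume with a warning.
    """
    tetA = _ensure_positive(np.asarray(tetA, dtype=float))
    tetB = _ensure_positive(np.asarray(tetB, dtype=float))
    scale = max(np.ptp(tetA), np.ptp(tetB))
    if scale == 0.0:
        warnings.warn("degenerate tetrahedron in intersection test")
        return 0.0, np.zeros(3)
    for tet in (tetA, tetB):
        d = tet[1:] - tet[0]
        c = _cross3(d[1], d[2])
        vol6 = d[0, 0] * c[0] + d[0, 1] * c[1] + d[0, 2] * c[2]
        if abs(vol6) / 6.0 < 1e-12 * scale**3:
            warnings.warn("degenerate tetrahedron in intersection test")
            return 0.0, np.zeros(3)
    eps = 1.0e-12 * scale

    # Quick reject on bounding boxes.
    if (tetA.min(axis=0) > tetB.max(axis=0) + eps).any() or \
       (tetB.min(axis=0) > tetA.max(axis=0) + eps).any():
        return 0.0, np.zeros(3)

    faces = _tet_faces(tetA)
    tb = [tuple(p) for p in tetB]
    for (i, j, k) in [(1, 2, 3), (0, 3, 2), (0, 1, 3), (0, 2, 1)]:
        p0, p1, p2 = tb[i], tb[j], tb[k]
        e1 = (p1[0] - p0[0], p1[1] - p0[1], p1[2] - p0[2])
        e2 = (p2[0] - p0[0], p2[1] - p0[1], p2[2] - p0[2])
        n = _cross3(e1, e2)
        norm = (n[0] * n[0] + n[1] * n[1] + n[2] * n[2]) ** 0.5
        if norm < eps * eps:
            warnings.warn("degenerate tetrahedron face in intersection test")
            return 0.0, np.zeros(3)
        nx, ny, nz = n[0] / norm, n[1] / norm, n[2] / norm
        d = nx * p0[0] + ny * p0[1] + nz * p0[2]
        new_faces = []
        cut_points = []
        any_outside = False
        for poly in faces:
            for p in poly:
                if nx * p[0] + ny * p[1] + nz * p[2] - d > eps:
                    any_outside = True
                    break
            clipped, cut = _clip_polygon(poly, (nx, ny, nz), d, eps)
            if len(clipped) >= 3:
                new_faces.append(clipped)
            cut_points.extend(cut)
        if not new_faces:
            return 0.0, np.zeros(3)
        # A cap face is only needed when the plane actually removed
        # material; otherwise (plane touching a face/vertex) the kept
        # faces already close the polyhedron.
        if any_outside and len(cut_points) >= 3:
            m = len(cut_points)
            ccx = sum(p[0] for p in cut_points) / m
            ccy = sum(p[1] for p in cut_points) / m
            ccz = sum(p[2] for p in cut_points) / m
            rx = cut_points[0][0] - ccx
            ry = cut_points[0][1] - ccy
            rz = cut_points[0][2] - ccz
            rn = (rx * rx + ry * ry + rz * rz) ** 0.5
            if rn > eps:
                ux, uy, uz = rx / rn, ry / rn, rz / rn
                # v = n x u completes the in-plane basis.
                vx, vy, vz = _cross3((nx, ny, nz), (ux, uy, uz))
                ang = []
                for p in cut_points:
                    qx, qy, qz = p[0] - ccx, p[1] - ccy, p[2] - ccz
                    ang.append(math.atan2(
                        qx * vx + qy * vy + qz * vz,
                        qx * ux + qy * uy + qz * uz))
                cap = [p for _, p in sorted(zip(ang, cut_points),
                                            key=lambda t: t[0])]
                # Deduplicate consecutive near-identical points.
                dedup = []
                for p in cap:
                    if not dedup or (abs(p[0] - dedup[-1][0])
                                     + abs(p[1] - dedup[-1][1])
                                     + abs(p[2] - dedup[-1][2])) > eps:
                        dedup.append(p)
                cap = dedup
                if len(cap) >= 3:
                    # Cap normal must point outward, i.e. along +n.
                    e1 = (cap[1][0] - cap[0][0], cap[1][1] - cap[0][1],
                          cap[1][2] - cap[0][2])
                    e2 = (cap[2][0] - cap[0][0], cap[2][1] - cap[0][1],
                          cap[2][2] - cap[0][2])
                    cn = _cross3(e1, e2)
                    if cn[0] * nx + cn[1] * ny + cn[2] * nz < 0:
                        cap = cap[::-1]
                    new_faces.append(cap)
        faces = new_faces
    vol, cent = _polyhedron_volume_centroid(faces)
    return max(vol, 0.0), cent


def tet_intersection_volume(tetA, tetB) -> float:
    """Intersection volume of two tetrahedra; symmetric in its arguments."""
    return tet_intersection_volume_centroid(tetA, tetB)[0]


# ---------------------------------------------------------------------------
# Linked-cell candidate search
# ---------------------------------------------------------------------------

@dataclass
class VoxelGrid:
    """Cuboidal linked-cell tiling of face centroids."""

    voxel_size: float
    cells: dict = field(default_factory=dict)

    def build(self, centroids: np.ndarray) -> None:
        if self.voxel_size <= 0:
            raise ValueError("voxel size must be positive")
        self.cells = {}
        keys = np.floor(centroids / self.voxel_size).astype(np.int64)
        for i, key in enumerate(map(tuple, keys)):
            self.cells.setdefault(key, []).append(i)

    def neighbour_pairs(self):
        """All index pairs (i < j) in the same or adjacent voxels."""
        offsets = [(dx, dy, dz)
                   for dx in (-1, 0, 1) for dy in (-1, 0, 1)
                   for dz in (-1, 0, 1)]
        half = [o for o in offsets if o > (0, 0, 0)]
        pairs = []
        for key, members in self.cells.items():
            m = len(members)
            for a in range(m):
                for b in range(a + 1, m):
                    pairs.append((members[a], members[b]))
            for off in half:
                nb = (key[0] + off[0], key[1] + off[1], key[2] + off[2])
                other = self.cells.get(nb)
                if other:
                    for i in members:
                        for j in other:
                            pairs.append((i, j) if i < j else (j, i))
        return pairs


def candidate_face_pairs(grid: VoxelGrid, centroids, normals, types,
                         blob_ids, allow_intra: bool = False):
    """Face pairs in adjacent voxels that face each other and are active.

    Filters: both types active (t != -1), normals opposed (n1.n2 < 0) and,
    unless ``allow_intra``, faces belonging to different bodies.
    """
    out = []
    for i, j in grid.neighbour_pairs():
        if types[i] < 0 or types[j] < 0:
            continue
        if not allow_intra and blob_ids[i] == blob_ids[j]:
            continue
        if np.dot(normals[i], normals[j]) < 0.0:
            out.append((i, j))
    return out


# ---------------------------------------------------------------------------
# Force terms
# ---------------------------------------------------------------------------

def _barycentric(tet, p):
    T = np.column_stack([tet[1] - tet[0], tet[2] - tet[0], tet[3] - tet[0]])
    w = np.linalg.solve(T, p - tet[0])
    return np.array([1.0 - w.sum(), w[0], w[1], w[2]])


def steric_forces(element_pairs, positions_a, positions_b, k_steric,
                  grad_step_rel: float = 1.0e-3):
    """Steric repulsion between overlapping tetrahedra of two bodies.

    ``element_pairs`` is a list of ``(tet_nodes_a, tet_nodes_b)`` index
    quadruples into the two position arrays.  Returns per-body nodal force
    arrays, the steric energy ``k_steric * sum(V)`` and the total overlap
    volume.  The force is the central-difference gradient of the overlap
    volume under rigid relative displacement, applied at the overlap
    centroid and linearly interpolated onto the 4 + 4 element nodes.
    """
    fa = np.zeros_like(positions_a)
    fb = np.zeros_like(positions_b)
    total_volume = 0.0
    for nodes_a, nodes_b in element_pairs:
        ta = positions_a[list(nodes_a)]
        tb = positions_b[list(nodes_b)]
        vol, centre = tet_intersection_volume_centroid(ta, tb)
        if vol <= 0.0:
            continue
        total_volume += vol
        edges = [np.linalg.norm(ta[i] - ta[j])
                 for i in range(4) for j in range(i + 1, 4)]
        edges += [np.linalg.norm(tb[i] - tb[j])
                  for i in range(4) for j in range(i + 1, 4)]
        h = grad_step_rel * min(e for e in edges if e > 0)
        grad = np.zeros(3)
        for ax in range(3):
            shift = np.zeros(3)
            shift[ax] = h
            vp = tet_intersection_volume(ta + shift, tb)
            vm = tet_intersection_volume(ta - shift, tb)
            grad[ax] = (vp - vm) / (2.0 * h)
        force_a = -k_steric * grad          # force on body A
        wa = _barycentric(ta, centre)
        wb = _barycentric(tb, centre)
        for i, n in enumerate(nodes_a):
            fa[n] += wa[i] * force_a
        for i, n in enumerate(nodes_b):
            fb[n] -= wb[i] * force_a
    return fa, fb, k_steric * total_volume, total_volume


@dataclass
class LJParamMatrix:
    """Per-type-pair Lennard-Jones surface parameters.

    ``r_eq`` (m) is the equilibrium distance, ``eps`` (J/m^4) the depth of
    the energy-per-unit-area-squared well, stored symmetrically in (t, s).
    """

    r_eq: np.ndarray = field(
        default_factory=lambda: np.zeros((N_FACE_TYPES, N_FACE_TYPES)))
    eps: np.ndarray = field(
        default_factory=lambda: np.zeros((N_FACE_TYPES, N_FACE_TYPES)))
    cutoff: float = 5.0e-9

    def set_pair(self, t, s, r_eq, eps):
        self.r_eq[t, s] = self.r_eq[s, t] = r_eq
        self.eps[t, s] = self.eps[s, t] = eps

    def active(self, t, s) -> bool:
        return self.eps[t, s] > 0.0 and self.r_eq[t, s] > 0.0


def _lj_kernel(r, r_eq, eps, steric_mode):
    """Force (dU/dr with sign: positive = repulsive) and energy densities."""
    if steric_mode and r < r_eq:
        # Cubic transition continuous in force and energy at r_eq, zero
        # value and slope at r = 0; hands hard-core repulsion to the
        # steric term.
        a = 72.0 * eps / r_eq**4
        f = a * r**2 * (r_eq - r)
        # U(r) = -eps + int_r^req f ds
        anti = lambda s: a * (r_eq * s**3 / 3.0 - s**4 / 4.0)
        u = -eps + (anti(r_eq) - anti(r))
        return f, u
    x = r_eq / r
    f = 12.0 * eps / r_eq * (x**13 - x**7)
    u = eps * (x**12 - 2.0 * x**6)
    return f, u


def _face_quadrature(tri, order):
    """(points, weights) on a triangle; weights sum to 1."""
    if order == 1:
        return tri.mean(axis=0)[None, :], np.array([1.0])
    # Three-point midpoint rule (degree 2).
    pts = np.array([
        (tri[0] + tri[1]) / 2.0,
        (tri[1] + tri[2]) / 2.0,
        (tri[2] + tri[0]) / 2.0,
    ])
    return pts, np.full(3, 1.0 / 3.0)


def lj_face_forces(face_pairs, faces_a, faces_b, positions_a, positions_b,
                   type_pairs, params: LJParamMatrix,
                   steric_mode: bool = False, order: int = 1):
    """Lennard-Jones surface attraction between face pairs of two bodies.

    The double surface integral is approximated with ``order``-point
    quadrature on each triangle: E = sum w_i w_j A1 A2 U(|q_i - q_j|).
    Forces are distributed onto face nodes by shape-function weights.
    """
    fa = np.zeros_like(positions_a)
    fb = np.zeros_like(positions_b)
    energy = 0.0
    for (i, j), (t, s) in zip(face_pairs, type_pairs):
        if not params.active(t, s):
            continue
        r_eq = params.r_eq[t, s]
        eps = params.eps[t, s]
        tri1 = positions_a[list(faces_a[i])]
        tri2 = positions_b[list(faces_b[j])]
        a1 = 0.5 * np.linalg.norm(np.cross(tri1[1] - tri1[0], tri1[2] - tri1[0]))
        a2 = 0.5 * np.linalg.norm(np.cross(tri2[1] - tri2[0], tri2[2] - tri2[0]))
        q1, w1 = _face_quadrature(tri1, order)
        q2, w2 = _face_quadrature(tri2, order)
        for p1, wt1 in zip(q1, w1):
            for p2, wt2 in zip(q2, w2):
                dvec = p1 - p2
                r = np.linalg.norm(dvec)
                if r > params.cutoff or r == 0.0:
                    continue
                fmag, u = _lj_kernel(r, r_eq, eps, steric_mode)
                scale = wt1 * wt2 * a1 * a2
                energy += scale * u
                fvec = scale * fmag * dvec / r
                # Equal shape-function weights at the quadrature points used.
                for n in faces_a[i]:
                    fa[n] += fvec / 3.0
                for n in faces_b[j]:
                    fb[n] -= fvec / 3.0
    return fa, fb, energy


@dataclass
class Spring:
    """Hookean link between node ``node_a`` of blob ``blob_a`` and
    ``node_b`` of ``blob_b``: F = -k (|d| - l0) d_hat."""

    blob_a: int
    node_a: int
    blob_b: int
    node_b: int
    stiffness: float          # N/m
    rest_length: float        # m

    def __post_init__(self):
        if self.stiffness < 0:
            raise ValueError("spring stiffness must be non-negative")
        if (self.blob_a, self.node_a) == (self.blob_b, self.node_b):
            raise ValueError("spring endpoints must be distinct")


def spring_forces(springs, positions_list):
    """Forces and energy of node-node Hookean springs across blobs."""
    forces = [np.zeros_like(x) for x in positions_list]
    energy = 0.0
    for s in springs:
        xa = positions_list[s.blob_a][s.node_a]
        xb = positions_list[s.blob_b][s.node_b]
        d = xa - xb
        r = np.linalg.norm(d)
        if r == 0.0:
            if s.rest_length > 0.0:
                warnings.warn("coincident spring endpoints with l0 > 0; "
                              "skipping undefined force")
            continue
        f = -s.stiffness * (r - s.rest_length) * d / r
        forces[s.blob_a][s.node_a] += f
        forces[s.blob_b][s.node_b] -= f
        energy += 0.5 * s.stiffness * (r - s.rest_length) ** 2
    return forces, energy


class BeadSet:
    """Pseudo-particle beads embedded in the meshes, with tabulated
    pair potentials.

    Each bead is permanently bound to the element whose centroid is closest
    to its initial position; its position follows the element by
    barycentric interpolation and the pair forces are spread back onto the
    element nodes with the same weights.  Tables map a type pair to columns
    (r, F[, E]); a missing pair means a null interaction.  Distances beyond
    the table are clamped to the last entry (with a warning).
    """

    def __init__(self, bead_positions, bead_types, bead_blobs, models,
                 tables):
        self.types = np.asarray(bead_types, dtype=np.intp)
        self.blobs = np.asarray(bead_blobs, dtype=np.intp)
        self.tables = {}
        for key, tab in tables.items():
            key = tuple(sorted(key))
            tab = np.asarray(tab, dtype=float)
            if tab.ndim != 2 or tab.shape[1] < 2:
                raise ValueError("bead table needs columns (r, F[, E])")
            r = tab[:, 0]
            if np.any(np.diff(r) <= 0):
                raise ValueError("bead table distances must increase")
            F = tab[:, 1]
            if tab.shape[1] >= 3:
                E = tab[:, 2]
            else:
                # Integrate F = -dE/dr from the outer end (E -> 0).
                E = np.concatenate([
                    np.cumsum(((F[1:] + F[:-1]) / 2.0 * np.diff(r))[::-1])[::-1],
                    [0.0],
                ])
            self.tables[key] = (r, F, E)
        self.host_element = np.empty(len(self.types), dtype=np.intp)
        self.weights = np.empty((len(self.types), 4))
        for i, (p, b) in enumerate(zip(np.asarray(bead_positions, float),
                                       self.blobs)):
            model = models[b]
            x = model.reference_positions
            cents = x[model.elements].mean(axis=1)
            e = int(np.argmin(((cents - p) ** 2).sum(axis=1)))
            self.host_element[i] = e
            self.weights[i] = _barycentric(x[model.elements[e]], p)
        self.models = models

    def positions(self, positions_list) -> np.ndarray:
        out = np.empty((len(self.types), 3))
        for i in range(len(self.types)):
            model = self.models[self.blobs[i]]
            nodes = model.elements[self.host_element[i]]
            out[i] = self.weights[i] @ positions_list[self.blobs[i]][nodes]
        return out

    def compute(self, positions_list):
        forces = [np.zeros_like(x) for x in positions_list]
        energy = 0.0
        pos = self.positions(positions_list)
        n = len(self.types)
        for i in range(n):
            for j in range(i + 1, n):
                if (self.blobs[i] == self.blobs[j]
                        and self.host_element[i] == self.host_element[j]):
                    continue   # no self-interaction within one element
                key = tuple(sorted((int(self.types[i]), int(self.types[j]))))
                tab = self.tables.get(key)
                if tab is None:
                    continue
                r_tab, F_tab, E_tab = tab
                d = pos[i] - pos[j]
                r = np.linalg.norm(d)
                if r == 0.0:
                    continue
                if r > r_tab[-1]:
                    warnings.warn("bead distance beyond table range; "
                                  "clamping to last entry")
                    r_eval = r_tab[-1]
                else:
                    r_eval = max(r, r_tab[0])
                fmag = float(np.interp(r_eval, r_tab, F_tab))
                energy += float(np.interp(r_eval, r_tab, E_tab))
                fvec = fmag * d / r
                for b, sgn in ((i, 1.0), (j, -1.0)):
                    model = self.models[self.blobs[b]]
                    nodes = model.elements[self.host_element[b]]
                    for a in range(4):
                        forces[self.blobs[b]][nodes[a]] += (
                            sgn * self.weights[b, a] * fvec)
        return forces, energy


def bead_forces(beadset: "BeadSet", positions_list):
    """Nodal forces and energy of all tabulated bead-bead interactions."""
    return beadset.compute(positions_list)


# ---------------------------------------------------------------------------
# The full inter-body force aggregator
# ---------------------------------------------------------------------------

class InteractionSet:
    """Aggregates all O_p force sources for a multi-blob simulation.

    Parameters
    ----------
    models : list of ContinuumModel (one per blob, in simulator order)
    steric : enable volume-overlap repulsion between surface elements
    k_steric : energy per overlap volume, J/m^3
    lj : optional LJParamMatrix enabling surface Lennard-Jones forces
    springs : list of Spring
    beads : optional BeadSet
    voxel_size : linked-cell size (m); default LJ cutoff, or half the
        longest surface edge for steric-only runs
    n_refresh : rebuild the voxel assignment every this many steps
    lj_order : quadrature order for the face-face integral (1 or 3)
    allow_intra : also test faces of the same body against each other
    """

    def __init__(self, models, steric=False, k_steric=1.0e6, lj=None,
                 springs=(), beads=None, voxel_size=None, n_refresh=10,
                 lj_order=1, allow_intra=False):
        self.models = list(models)
        self.steric = bool(steric)
        self.k_steric = float(k_steric)
        self.lj = lj
        self.springs = list(springs)
        self.beads = beads
        self.n_refresh = int(n_refresh)
        self.lj_order = int(lj_order)
        self.allow_intra = bool(allow_intra)

        # Global surface face table.
        self._face_nodes = []
        self._face_owner = []
        self._face_blob = []
        self._face_type = []
        for b, model in enumerate(self.models):
            mesh = model.mesh
            for f, owner, t in zip(mesh.surface_faces, mesh.surface_owner,
                                   mesh.face_types):
                self._face_nodes.append(tuple(int(v) for v in f))
                self._face_owner.append(int(owner))
                self._face_blob.append(b)
                self._face_type.append(int(t))
        self._face_blob = np.array(self._face_blob, dtype=np.intp)
        self._face_type = np.array(self._face_type, dtype=np.intp)
        self._face_owner = np.array(self._face_owner, dtype=np.intp)
        self._face_nodes_arr = (np.array(self._face_nodes, dtype=np.intp)
                                if self._face_nodes else
                                np.empty((0, 3), dtype=np.intp))
        # Per-blob node index offsets for vectorised gathering.
        self._node_offsets = np.cumsum(
            [0] + [m.n_nodes for m in self.models])

        if voxel_size is None:
            if lj is not None:
                voxel_size = lj.cutoff
            else:
                longest = 0.0
                for model in self.models:
                    mesh = model.mesh
                    x = mesh.nodes * 1.0e-9
                    for f in mesh.surface_faces:
                        tri = x[f]
                        for a in range(3):
                            longest = max(longest, np.linalg.norm(
                                tri[a] - tri[(a + 1) % 3]))
                voxel_size = max(longest, 1.0e-10)
        self.grid = VoxelGrid(float(voxel_size))
        self._raw_pairs = None
        self._last_build = None
        self.last_overlap_volume = 0.0

    def _centroids_normals(self, positions_list):
        allpos = np.concatenate(positions_list, axis=0)
        gidx = self._face_nodes_arr + self._node_offsets[self._face_blob][:, None]
        tri = allpos[gidx]                               # (F, 3, 3)
        cents = tri.mean(axis=1)
        norms = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        return cents, norms

    def _rebuild(self, positions_list):
        cents, _ = self._centroids_normals(positions_list)
        self.grid.build(cents)
        pairs = self.grid.neighbour_pairs()
        self._raw_pairs = (np.array(pairs, dtype=np.intp) if pairs
                           else np.empty((0, 2), dtype=np.intp))

    def compute(self, positions_list, step):
        forces = [np.zeros_like(x) for x in positions_list]
        energy = 0.0
        need_faces = self.steric or (self.lj is not None)
        if need_faces:
            if self._raw_pairs is None or self._last_build is None or \
                    step - self._last_build >= self.n_refresh:
                self._rebuild(positions_list)
                self._last_build = step
            cents, norms = self._centroids_normals(positions_list)
            fb, ft = self._face_blob, self._face_type
            pij = self._raw_pairs
            if len(pij):
                keep = (ft[pij[:, 0]] >= 0) & (ft[pij[:, 1]] >= 0)
                if not self.allow_intra:
                    keep &= fb[pij[:, 0]] != fb[pij[:, 1]]
                facing = np.einsum("pi,pi->p", norms[pij[:, 0]],
                                   norms[pij[:, 1]]) < 0.0
                active = pij[keep & facing]
            else:
                active = np.empty((0, 2), dtype=np.intp)
            active_pairs = active

            if self.steric:
                self.last_overlap_volume = 0.0
            if self.steric and len(active):
                ep = np.unique(np.stack([
                    fb[active[:, 0]], self._face_owner[active[:, 0]],
                    fb[active[:, 1]], self._face_owner[active[:, 1]],
                ], axis=1), axis=0)
                # Vectorised bounding-box rejection before exact clipping.
                allpos = np.concatenate(positions_list, axis=0)
                off = self._node_offsets
                na = np.stack([self.models[b].elements[e]
                               for b, e in zip(ep[:, 0], ep[:, 1])])
                nb = np.stack([self.models[b].elements[e]
                               for b, e in zip(ep[:, 2], ep[:, 3])])
                xa = allpos[na + off[ep[:, 0]][:, None]]
                xb = allpos[nb + off[ep[:, 2]][:, None]]
                overlap = ((xa.min(axis=1) <= xb.max(axis=1)).all(axis=1)
                           & (xb.min(axis=1) <= xa.max(axis=1)).all(axis=1))
                for (ba, ea, bb, eb) in ep[overlap]:
                    ta = self.models[ba].elements[ea]
                    tb = self.models[bb].elements[eb]
                    fa, fbb, en, vol = steric_forces(
                        [(ta, tb)], positions_list[ba], positions_list[bb],
                        self.k_steric)
                    forces[ba] += fa
                    forces[bb] += fbb
                    energy += en
                    self.last_overlap_volume += vol

            if self.lj is not None and active_pairs:
                by_blobs = {}
                for i, j in active_pairs:
                    by_blobs.setdefault((fb[i], fb[j]), []).append((i, j))
                for (ba, bb), pairs in by_blobs.items():
                    faces_a = {i: self._face_nodes[i] for i, _ in pairs}
                    faces_b = {j: self._face_nodes[j] for _, j in pairs}
                    tp = [(ft[i], ft[j]) for i, j in pairs]
                    fa, fbb, en = lj_face_forces(
                        pairs, faces_a, faces_b,
                        positions_list[ba], positions_list[bb], tp, self.lj,
                        steric_mode=self.steric, order=self.lj_order)
                    forces[ba] += fa
                    forces[bb] += fbb
                    energy += en

        if self.springs:
            sf, en = spring_forces(self.springs, positions_list)
            for f, s in zip(forces, sf):
                f += s
            energy += en
        if self.beads is not None:
            bf, en = self.beads.compute(positions_list)
            for f, s in zip(forces, bf):
                f += s
            energy += en
        return forces, energy
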