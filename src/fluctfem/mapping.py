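"""Continuum-to-atomistic mapping (the atomic mapper).

An atomic structure is bound to the tetrahedral mesh once, by barycentric
coordinates: each atom is assigned the element containing it (atoms outside
every element get the nearest element, with extrapolated weights that sum
to one but may leave [0, 1]).  Replaying a mesh trajectory through the map
yields a pseudo-atomistic trajectory in which every atom follows the linear
interpolation of its host element's nodes, written as a multi-MODEL PDB.

Mesh coordinates are nanometres; PDB files use angstroms.
"""

from __future__ import annotations

import numpy as np

import biotite.structure as struc
import biotite.structure.io.pdb as pdbio

from .constants import NM

__all__ = ["StructureMap", "build_map", "map_trajectory",
           "load_pdb_coords", "write_pdb_frames", "save_map", "load_map"]

_INSIDE_TOL = -1.0e-9


class StructureMap:
    """Per-atom host element indices and barycentric weights."""

    def __init__(self, element_index, weights, n_elements):
        self.element_index = np.asarray(element_index, dtype=np.intp)
        self.weights = np.asarray(weights, dtype=float)
        self.n_elements = int(n_elements)
        if self.weights.shape != (len(self.element_index), 4):
            raise ValueError("weights must be (n_atoms, 4)")
        if not np.allclose(self.weights.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("barycentric weights must sum to 1")

    @property
    def n_atoms(self) -> int:
        return len(self.element_index)

    def interior_mask(self) -> np.ndarray:
        return (self.weights >= _INSIDE_TOL).all(axis=1)


def _all_barycentric(mesh, points):
    """(n_atoms, E, 4) barycentric weights of every point in every element."""
    x = mesh.nodes[mesh.elements]                    # (E, 4, 3)
    T = (x[:, 1:] - x[:, :1]).transpose(0, 2, 1)     # (E, 3, 3)
    Tinv = np.linalg.inv(T)
    rel = points[:, None, :] - x[None, :, 0, :]      # (A, E, 3)
    w123 = np.einsum("eij,aej->aei", Tinv, rel)
    w0 = 1.0 - w123.sum(axis=2, keepdims=True)
    return np.concatenate([w0, w123], axis=2)


def build_map(atom_coords_nm, mesh) -> StructureMap:
    """Bind atoms (nm) to the mesh by barycentric coordinates.

    Atoms inside an element (weights >= -1e-9, ties broken by lowest
    element index) are interpolated; exterior atoms extrapolate from the
    element with the nearest centroid.
    """
    pts = np.asarray(atom_coords_nm, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) == 0:
        raise ValueError("atom coordinates must be a non-empty (A, 3) array")
    if mesh.n_elements == 0:
        raise ValueError("empty mesh")
    W = _all_barycentric(mesh, pts)
    min_w = W.min(axis=2)                            # (A, E)
    inside = min_w >= _INSIDE_TOL
    element = np.empty(len(pts), dtype=np.intp)
    weights = np.empty((len(pts), 4))
    cents = mesh.nodes[mesh.elements].mean(axis=1)
    for a in range(len(pts)):
        hits = np.flatnonzero(inside[a])
        if len(hits):
            e = int(hits[0])                         # lowest element index
        else:
            e = int(np.argmin(((cents - pts[a]) ** 2).sum(axis=1)))
        element[a] = e
        weights[a] = W[a, e]
    return StructureMap(element, weights, mesh.n_elements)


def map_frame(smap: StructureMap, mesh_elements, node_coords) -> np.ndarray:
    """Atom positions from one frame of node coordinates (same units)."""
    nodes = mesh_elements[smap.element_index]        # (A, 4)
    return np.einsum("aw,awj->aj", smap.weights, node_coords[nodes])


def map_trajectory(smap: StructureMap, mesh, traj, blob: int = 0):
    """Per-frame atom coordinate arrays (nm) from a mesh trajectory."""
    if smap.n_elements != mesh.n_elements:
        raise ValueError("map was built against a different mesh topology")
    frames = []
    for frame in traj.frames:
        coords = np.asarray(frame[blob])
        if len(coords) != mesh.n_nodes:
            raise ValueError("trajectory node count does not match the mesh")
        frames.append(map_frame(smap, mesh.elements, coords))
    return frames


# ---------------------------------------------------------------------------
# PDB and .map file I/O
# ---------------------------------------------------------------------------

def load_pdb_coords(path) -> np.ndarray:
    """Atom coordinates (nm) of the first model of a PDB file."""
    pdb = pdbio.PDBFile.read(str(path))
    atoms = pdb.get_structure(model=1)
    return atoms.coord / 10.0                        # angstrom -> nm


def write_pdb_frames(path, frames_nm, element="C") -> None:
    """Write pseudo-atomic frames (nm) as a multi-MODEL PDB (angstrom)."""
    frames_nm = [np.asarray(f) for f in frames_nm]
    n = len(frames_nm[0])
    atoms = struc.AtomArray(n)
    atoms.coord = frames_nm[0] * 10.0
    atoms.atom_name = np.full(n, "CA", dtype="U6")
    atoms.res_name = np.full(n, "GLY", dtype="U5")
    atoms.res_id = np.arange(1, n + 1)
    atoms.chain_id = np.full(n, "A", dtype="U4")
    atoms.element = np.full(n, element, dtype="U2")
    stack = struc.stack(
        [atoms.copy() for _ in frames_nm]
    )
    for i, f in enumerate(frames_nm):
        stack.coord[i] = f * 10.0
    pdb = pdbio.PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def save_map(path, smap: StructureMap) -> None:
    """Text .map file: atom index, element index, four weights."""
    with open(path, "w") as fh:
        fh.write(f"{smap.n_atoms} {smap.n_elements}\n")
        for a in range(smap.n_atoms):
            w = smap.weights[a]
            fh.write(f"{a} {smap.element_index[a]} "
                     f"{w[0]:.17g} {w[1]:.17g} {w[2]:.17g} {w[3]:.17g}\n")


def load_map(path) -> StructureMap:
    with open(path) as fh:
        header = fh.readline().split()
        n_atoms, n_elements = int(header[0]), int(header[1])
        element = np.empty(n_atoms, dtype=np.intp)
        weights = np.empty((n_atoms, 4))
        for line in fh:
            f = line.split()
            a = int(f[0])
            element[a] = int(f[1])
            weights[a] = [float(v) for v in f[2:6]]
    return StructureMap(element, weights, n_elements)
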