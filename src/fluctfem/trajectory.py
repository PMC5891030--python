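"""Trajectory, measurement and checkpoint file formats (all plain text).

Trajectory files store node coordinates (and velocities for inertial runs)
in nanometres / nanometres-per-nanosecond, one block per recorded frame.
Checkpoints store the full simulation state -- positions, velocities, step
counter and the random-number-generator state of every body -- with floats
serialised in C99 hex notation so a restart continues bit-for-bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .constants import NM, NS

__all__ = ["Trajectory", "Measurements", "save_checkpoint", "load_checkpoint"]


@dataclass
class Trajectory:
    """Recorded frames of a simulation.

    Attributes
    ----------
    times : list of float, ns
    frames : list of list of (N_b, 3) arrays, nm
        One coordinate array per blob per frame.
    velocities : list of list of arrays or None, nm/ns
    meta : dict
        Provenance header fields (dt, n_check, seed, ...).
    """

    times: list = field(default_factory=list)
    frames: list = field(default_factory=list)
    velocities: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_blobs(self) -> int:
        return len(self.frames[0]) if self.frames else 0

    def blob_coords(self, b: int = 0) -> np.ndarray:
        """(frames, N, 3) array of one blob's coordinates, nm."""
        return np.stack([f[b] for f in self.frames])

    def append(self, time_ns, coords, velocities=None):
        self.times.append(float(time_ns))
        self.frames.append([np.array(c, dtype=float) for c in coords])
        if velocities is not None:
            self.velocities.append([np.array(v, dtype=float) for v in velocities])

    # -- text format ----------------------------------------------------

    def write(self, path) -> None:
        has_vel = bool(self.velocities)
        with open(path, "w") as fh:
            fh.write("# fluctfem trajectory\n")
            for k, v in self.meta.items():
                fh.write(f"# {k}: {v}\n")
            fh.write(f"blobs {self.n_blobs}\n")
            fh.write("nodes " + " ".join(str(len(c)) for c in self.frames[0]) + "\n")
            fh.write(f"velocities {1 if has_vel else 0}\n")
            for k, (t, coords) in enumerate(zip(self.times, self.frames)):
                fh.write(f"frame {k} time {t:.9e}\n")
                for b, c in enumerate(coords):
                    fh.write(f"blob {b}\n")
                    if has_vel:
                        v = self.velocities[k][b]
                        for (x, y, z), (vx, vy, vz) in zip(c, v):
                            fh.write(f"{x:.10e} {y:.10e} {z:.10e} "
                                     f"{vx:.10e} {vy:.10e} {vz:.10e}\n")
                    else:
                        for x, y, z in c:
                            fh.write(f"{x:.10e} {y:.10e} {z:.10e}\n")

    @classmethod
    def read(cls, path) -> "Trajectory":
        traj = cls()
        with open(path) as fh:
            lines = [ln.rstrip("\n") for ln in fh]
        i = 0
        while i < len(lines) and lines[i].startswith("#"):
            if ":" in lines[i]:
                k, _, v = lines[i][1:].partition(":")
                traj.meta[k.strip()] = v.strip()
            i += 1
        n_blobs = int(lines[i].split()[1]); i += 1
        n_nodes = [int(s) for s in lines[i].split()[1:]]; i += 1
        has_vel = bool(int(lines[i].split()[1])); i += 1
        if len(n_nodes) != n_blobs:
            raise ValueError(f"{path}: node-count header does not match blob count")
        while i < len(lines):
            if not lines[i].startswith("frame"):
                if lines[i].strip() == "":
                    i += 1
                    continue
                raise ValueError(f"{path}:{i+1}: expected a frame header")
            t = float(lines[i].split()[3]); i += 1
            coords, vels = [], []
            for b in range(n_blobs):
                i += 1  # "blob b" line
                rows = np.array(
                    [[float(v) for v in lines[i + r].split()]
                     for r in range(n_nodes[b])]
                )
                i += n_nodes[b]
                coords.append(rows[:, :3])
                if has_vel:
                    vels.append(rows[:, 3:6])
            traj.append(t, coords, vels if has_vel else None)
        return traj


class Measurements:
    """Tab-separated measurement table with named columns."""

    def __init__(self, columns):
        self.columns = list(columns)
        self.rows = []

    def append(self, **values):
        self.rows.append([values[c] for c in self.columns])

    def column(self, name) -> np.ndarray:
        j = self.columns.index(name)
        return np.array([r[j] for r in self.rows], dtype=float)

    def as_dict(self) -> dict:
        return {c: self.column(c) for c in self.columns}

    def write(self, path, meta=None) -> None:
        with open(path, "w") as fh:
            for k, v in (meta or {}).items():
                fh.write(f"# {k}: {v}\n")
            fh.write("\t".join(self.columns) + "\n")
            for row in self.rows:
                fh.write("\t".join(f"{v:.10e}" for v in row) + "\n")

    @classmethod
    def read(cls, path) -> "Measurements":
        with open(path) as fh:
            lines = [ln for ln in fh if not ln.startswith("#")]
        m = cls(lines[0].split())
        for ln in lines[1:]:
            if ln.strip():
                m.rows.append([float(v) for v in ln.split()])
        return m


def _hex_array(a: np.ndarray) -> list:
    return [float(v).hex() for v in np.asarray(a, dtype=float).ravel()]


def _unhex_array(vals, shape) -> np.ndarray:
    return np.array([float.fromhex(v) for v in vals]).reshape(shape)


def save_checkpoint(path, state) -> None:
    """Serialise a simulation state dict (see Simulator.checkpoint)."""
    doc = {
        "format": "fluctfem-checkpoint-1",
        "step": state["step"],
        "time": float(state["time"]).hex(),
        "blobs": [],
    }
    for b in state["blobs"]:
        entry = {
            "positions": _hex_array(b["positions"]),
            "shape": list(np.asarray(b["positions"]).shape),
            "rng_state": b["rng_state"],
        }
        if b.get("velocities") is not None:
            entry["velocities"] = _hex_array(b["velocities"])
        doc["blobs"].append(entry)
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_checkpoint(path) -> dict:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format") != "fluctfem-checkpoint-1":
        raise ValueError(f"{path}: not a fluctfem checkpoint")
    blobs = []
    for b in doc["blobs"]:
        shape = tuple(b["shape"])
        entry = {
            "positions": _unhex_array(b["positions"], shape),
            "rng_state": b["rng_state"],
            "velocities": (_unhex_array(b["velocities"], shape)
                           if "velocities" in b else None),
        }
        blobs.append(entry)
    return {"step": doc["step"], "time": float.fromhex(doc["time"]),
            "blobs": blobs}
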