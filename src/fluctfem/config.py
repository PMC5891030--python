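"""INI-style simulation configuration: parsing, validation, assembly.

A config file has a ``[simulation]`` block (time-step, duration, output,
temperature, solvent), one ``[material.<name>]`` block per material, one
``[blob.<i>]`` block per body (mesh paths, material, scheme, placement,
pins) and an optional ``[interactions]`` block (steric constant, LJ and
spring files, voxels, beads).  Parsing is strict: unknown keys are errors,
every referenced file must exist, and the fully-resolved configuration
(defaults included) can be echoed back for provenance.
"""

from __future__ import annotations

import configparser
import hashlib
import os
from dataclasses import dataclass, field

import numpy as np

from .constants import NM
from .continuum import ContinuumModel
from .integrators import SimBlob, Simulator
from .interactions import InteractionSet, LJParamMatrix, Spring, BeadSet
from .materials import DragModel, Material
from .meshkit import load_mesh

__all__ = ["ConfigError", "SimulationConfig", "parse_config"]


class ConfigError(ValueError):
    pass


_SIM_KEYS = {
    "dt": (float, None), "n_steps": (int, None), "n_check": (int, 100),
    "temperature": (float, 300.0), "seed": (int, 0), "noise": (bool, True),
    "scheme": (str, "brownian"), "solvent_viscosity": (float, 0.0),
    "trajectory": (str, ""), "measurements": (str, ""),
    "checkpoint": (str, ""),
}

_MAT_KEYS = {"density", "youngs_modulus", "poisson_ratio", "shear_modulus",
             "bulk_modulus", "shear_viscosity", "bulk_viscosity"}

_BLOB_KEYS = {"mesh", "material", "scheme", "lumped_mass", "pin_file",
              "translate_nm", "rotate_deg", "velocity_m_s",
              "drag_radius_nm"}

_INTER_KEYS = {"steric", "k_steric", "lj_file", "lj_cutoff_nm", "lj_order",
               "springs_file", "voxel_size_nm", "n_refresh", "allow_intra",
               "beads_file"}


def _parse_bool(s):
    v = str(s).strip().lower()
    if v in ("1", "yes", "true", "on"):
        return True
    if v in ("0", "no", "false", "off"):
        return False
    raise ConfigError(f"invalid boolean {s!r}")


def _vector(s, n=3):
    parts = str(s).split()
    if len(parts) != n:
        raise ConfigError(f"expected {n} numbers, got {s!r}")
    return np.array([float(p) for p in parts])


@dataclass
class BlobConfig:
    mesh_base: str
    material: str
    scheme: str
    lumped_mass: bool = False
    pin_file: str = ""
    translate_nm: np.ndarray = field(default_factory=lambda: np.zeros(3))
    rotate_deg: np.ndarray = field(default_factory=lambda: np.zeros(3))
    velocity_m_s: np.ndarray = field(default_factory=lambda: np.zeros(3))
    drag_radius_nm: float = 1.0


@dataclass
class SimulationConfig:
    dt: float
    n_steps: int
    n_check: int
    temperature: float
    seed: int
    noise: bool
    solvent_viscosity: float
    trajectory: str
    measurements: str
    checkpoint: str
    materials: dict
    blobs: list
    steric: bool = False
    k_steric: float = 1.0e6
    lj_file: str = ""
    lj_cutoff_nm: float = 5.0
    lj_order: int = 1
    springs_file: str = ""
    voxel_size_nm: float = 0.0
    n_refresh: int = 10
    allow_intra: bool = False
    beads_file: str = ""
    base_dir: str = "."
    source_text: str = ""

    def echo(self) -> str:
        """Fully-resolved configuration, defaults included."""
        lines = ["[simulation]"]
        for key in ("dt", "n_steps", "n_check", "temperature", "seed",
                    "noise", "solvent_viscosity", "trajectory",
                    "measurements", "checkpoint"):
            lines.append(f"{key} = {getattr(self, key)}")
        for name, m in sorted(self.materials.items()):
            lines.append(f"[material.{name}]")
            lines.append(f"density = {m.density}")
            lines.append(f"shear_modulus = {m.shear_modulus}")
            lines.append(f"bulk_modulus = {m.bulk_modulus}")
            lines.append(f"shear_viscosity = {m.shear_viscosity}")
            lines.append(f"bulk_viscosity = {m.bulk_viscosity}")
        for i, b in enumerate(self.blobs):
            lines.append(f"[blob.{i}]")
            lines.append(f"mesh = {b.mesh_base}")
            lines.append(f"material = {b.material}")
            lines.append(f"scheme = {b.scheme}")
            lines.append(f"lumped_mass = {b.lumped_mass}")
            lines.append(f"pin_file = {b.pin_file}")
            lines.append("translate_nm = " + " ".join(map(str, b.translate_nm)))
            lines.append("rotate_deg = " + " ".join(map(str, b.rotate_deg)))
            lines.append("velocity_m_s = " + " ".join(map(str, b.velocity_m_s)))
            lines.append(f"drag_radius_nm = {b.drag_radius_nm}")
        lines.append("[interactions]")
        for key in ("steric", "k_steric", "lj_file", "lj_cutoff_nm",
                    "lj_order", "springs_file", "voxel_size_nm",
                    "n_refresh", "allow_intra", "beads_file"):
            lines.append(f"{key} = {getattr(self, key)}")
        return "\n".join(lines)

    def config_hash(self) -> str:
        return hashlib.sha256(self.echo().encode()).hexdigest()[:16]

    # ------------------------------------------------------------------

    def _path(self, p):
        return p if os.path.isabs(p) else os.path.join(self.base_dir, p)

    def build(self) -> Simulator:
        """Assemble the Simulator described by this configuration."""
        from scipy.spatial.transform import Rotation

        blobs = []
        models = []
        for bc in self.blobs:
            base = self._path(bc.mesh_base)
            face = base + ".face" if os.path.exists(base + ".face") else None
            mesh = load_mesh(base + ".node", base + ".ele", face)
            mat = self.materials[bc.material]
            drag = DragModel(
                solvent_viscosity=self.solvent_viscosity,
                node_radius=bc.drag_radius_nm * NM,
                temperature=self.temperature,
            )
            model = ContinuumModel(mesh, mat, drag)
            x = model.reference_positions.copy()
            if np.any(bc.rotate_deg):
                R = Rotation.from_euler("xyz", bc.rotate_deg,
                                        degrees=True).as_matrix()
                c = x.mean(axis=0)
                x = (x - c) @ R.T + c
            x = x + bc.translate_nm * NM
            pins = []
            if bc.pin_file:
                with open(self._path(bc.pin_file)) as fh:
                    pins = [int(t) for t in fh.read().split()]
            v0 = np.tile(bc.velocity_m_s, (mesh.n_nodes, 1))
            blob = SimBlob(model, scheme=bc.scheme, pinned=pins,
                           lumped_mass=bc.lumped_mass, positions=x,
                           velocities=v0 if bc.scheme == "langevin" else None)
            blobs.append(blob)
            models.append(model)

        interactions = None
        springs = []
        if self.springs_file:
            springs = _load_springs(self._path(self.springs_file))
        lj = None
        if self.lj_file:
            lj = _load_lj(self._path(self.lj_file), self.lj_cutoff_nm * NM)
        beads = None
        if self.beads_file:
            beads = _load_beads(self._path(self.beads_file), models,
                                self.base_dir)
        if self.steric or lj is not None or springs or beads is not None:
            interactions = InteractionSet(
                models, steric=self.steric, k_steric=self.k_steric, lj=lj,
                springs=springs, beads=beads,
                voxel_size=(self.voxel_size_nm * NM
                            if self.voxel_size_nm > 0 else None),
                n_refresh=self.n_refresh, lj_order=self.lj_order,
                allow_intra=self.allow_intra,
            )
        return Simulator(blobs, dt=self.dt, temperature=self.temperature,
                         seed=self.seed, interactions=interactions,
                         noise=self.noise)


def _load_springs(path):
    springs = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#")[0].strip()
            if not line:
                continue
            f = line.split()
            if len(f) != 6:
                raise ConfigError(f"{path}:{lineno}: expected "
                                  "'blob_a node_a blob_b node_b k l0_nm'")
            springs.append(Spring(int(f[0]), int(f[1]), int(f[2]), int(f[3]),
                                  float(f[4]), float(f[5]) * NM))
    return springs


def _load_lj(path, cutoff):
    lj = LJParamMatrix(cutoff=cutoff)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#")[0].strip()
            if not line:
                continue
            f = line.split()
            if len(f) != 4:
                raise ConfigError(f"{path}:{lineno}: expected "
                                  "'t s r_eq_nm eps'")
            lj.set_pair(int(f[0]), int(f[1]), float(f[2]) * NM, float(f[3]))
    return lj


def _load_beads(path, models, base_dir):
    """Bead file: header lines ``table <t> <s> <file>`` then rows
    ``blob type x y z`` (nm)."""
    tables = {}
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#")[0].strip()
            if not line:
                continue
            f = line.split()
            if f[0] == "table":
                if len(f) != 4:
                    raise ConfigError(f"{path}:{lineno}: expected "
                                      "'table t s file'")
                tab_path = f[3]
                if not os.path.isabs(tab_path):
                    tab_path = os.path.join(base_dir, tab_path)
                data = np.loadtxt(tab_path, ndmin=2)
                # Table distances are nm; convert to metres.
                data = data.copy()
                data[:, 0] *= NM
                tables[(int(f[1]), int(f[2]))] = data
            else:
                if len(f) != 5:
                    raise ConfigError(f"{path}:{lineno}: expected "
                                      "'blob type x y z'")
                rows.append((int(f[0]), int(f[1]),
                             np.array([float(v) for v in f[2:5]]) * NM))
    if not rows:
        return None
    return BeadSet(
        bead_positions=[r[2] for r in rows],
        bead_types=[r[1] for r in rows],
        bead_blobs=[r[0] for r in rows],
        models=models, tables=tables,
    )


def parse_config(path) -> SimulationConfig:
    """Parse and validate a config file; unknown keys are errors."""
    if not os.path.exists(path):
        raise ConfigError(f"config file not found: {path}")
    cp = configparser.ConfigParser(inline_comment_prefixes=("#", ";"))
    with open(path) as fh:
        text = fh.read()
    cp.read_string(text, source=str(path))
    base_dir = os.path.dirname(os.path.abspath(path))

    if "simulation" not in cp:
        raise ConfigError(f"{path}: missing [simulation] section")
    sim = cp["simulation"]
    for key in sim:
        if key not in _SIM_KEYS:
            raise ConfigError(f"{path}: unknown key '{key}' in [simulation]")
    values = {}
    for key, (typ, default) in _SIM_KEYS.items():
        if key in sim:
            raw = sim[key]
            values[key] = _parse_bool(raw) if typ is bool else typ(raw)
        elif default is None:
            raise ConfigError(f"{path}: missing required key '{key}' "
                              "in [simulation]")
        else:
            values[key] = default
    if values["dt"] <= 0:
        raise ConfigError(f"{path}: dt must be positive")
    if values["n_steps"] < 0:
        raise ConfigError(f"{path}: n_steps must be non-negative")
    if values["scheme"] not in ("brownian", "langevin"):
        raise ConfigError(f"{path}: invalid scheme '{values['scheme']}'")
    default_scheme = values.pop("scheme")

    materials = {}
    blob_sections = []
    inter = {}
    for section in cp.sections():
        if section == "simulation":
            continue
        if section.startswith("material."):
            name = section.split(".", 1)[1]
            block = cp[section]
            for key in block:
                if key not in _MAT_KEYS:
                    raise ConfigError(f"{path}: unknown key '{key}' in "
                                      f"[{section}]")
            dens = float(block.get("density", 1500.0))
            mus = float(block.get("shear_viscosity", 1.0e-3))
            mub = float(block.get("bulk_viscosity", 1.0e-3))
            if "youngs_modulus" in block or "poisson_ratio" in block:
                if "shear_modulus" in block or "bulk_modulus" in block:
                    raise ConfigError(
                        f"{path}: [{section}] mixes (E, nu) with (G, K)")
                E = float(block["youngs_modulus"])
                nu = float(block["poisson_ratio"])
                materials[name] = Material.from_young_poisson(
                    dens, E, nu, mus, mub)
            else:
                materials[name] = Material(
                    dens, float(block["shear_modulus"]),
                    float(block["bulk_modulus"]), mus, mub)
        elif section.startswith("blob."):
            blob_sections.append(section)
        elif section == "interactions":
            block = cp[section]
            for key in block:
                if key not in _INTER_KEYS:
                    raise ConfigError(f"{path}: unknown key '{key}' in "
                                      "[interactions]")
            inter = dict(block)
        else:
            raise ConfigError(f"{path}: unknown section [{section}]")

    if not blob_sections:
        raise ConfigError(f"{path}: at least one [blob.<i>] is required")
    blob_sections.sort(key=lambda s: int(s.split(".", 1)[1]))
    blobs = []
    for section in blob_sections:
        block = cp[section]
        for key in block:
            if key not in _BLOB_KEYS:
                raise ConfigError(f"{path}: unknown key '{key}' in "
                                  f"[{section}]")
        if "mesh" not in block:
            raise ConfigError(f"{path}: [{section}] needs a mesh path")
        if "material" not in block:
            raise ConfigError(f"{path}: [{section}] needs a material name")
        mat = block["material"]
        if mat not in materials:
            raise ConfigError(f"{path}: [{section}] references unknown "
                              f"material '{mat}'")
        scheme = block.get("scheme", default_scheme)
        if scheme not in ("brownian", "langevin"):
            raise ConfigError(f"{path}: invalid scheme '{scheme}' in "
                              f"[{section}]")
        bc = BlobConfig(
            mesh_base=block["mesh"], material=mat, scheme=scheme,
            lumped_mass=_parse_bool(block.get("lumped_mass", "no")),
            pin_file=block.get("pin_file", ""),
            translate_nm=_vector(block.get("translate_nm", "0 0 0")),
            rotate_deg=_vector(block.get("rotate_deg", "0 0 0")),
            velocity_m_s=_vector(block.get("velocity_m_s", "0 0 0")),
            drag_radius_nm=float(block.get("drag_radius_nm", 1.0)),
        )
        mesh_base = bc.mesh_base if os.path.isabs(bc.mesh_base) else \
            os.path.join(base_dir, bc.mesh_base)
        for ext in (".node", ".ele"):
            if not os.path.exists(mesh_base + ext):
                raise ConfigError(f"{path}: [{section}] mesh file "
                                  f"{mesh_base + ext} not found")
        if bc.pin_file:
            pf = bc.pin_file if os.path.isabs(bc.pin_file) else \
                os.path.join(base_dir, bc.pin_file)
            if not os.path.exists(pf):
                raise ConfigError(f"{path}: pin file {pf} not found")
        blobs.append(bc)

    cfg = SimulationConfig(
        materials=materials, blobs=blobs, base_dir=base_dir,
        source_text=text, **values)
    if inter:
        cfg.steric = _parse_bool(inter.get("steric", "no"))
        cfg.k_steric = float(inter.get("k_steric", 1.0e6))
        cfg.lj_file = inter.get("lj_file", "")
        cfg.lj_cutoff_nm = float(inter.get("lj_cutoff_nm", 5.0))
        cfg.lj_order = int(inter.get("lj_order", 1))
        if cfg.lj_order not in (1, 3):
            raise ConfigError(f"{path}: lj_order must be 1 or 3")
        cfg.springs_file = inter.get("springs_file", "")
        cfg.voxel_size_nm = float(inter.get("voxel_size_nm", 0.0))
        cfg.n_refresh = int(inter.get("n_refresh", 10))
        cfg.allow_intra = _parse_bool(inter.get("allow_intra", "no"))
        cfg.beads_file = inter.get("beads_file", "")
        for attr in ("lj_file", "springs_file", "beads_file"):
            p = getattr(cfg, attr)
            if p and not os.path.exists(cfg._path(p)):
                raise ConfigError(f"{path}: referenced file {p} not found")
    return cfg
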