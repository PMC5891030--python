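"""Material parameters, elastic-moduli conversions and per-region assignment.

The constitutive model is parameterised by shear and bulk moduli (G, K) and
shear and bulk dynamic viscosities; validation scenarios are usually quoted
in terms of Young's modulus E and Poisson ratio nu, so the standard
isotropic conversions are provided.  All quantities are SI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Material",
    "DragModel",
    "MaterialTable",
    "from_young_poisson",
    "to_young_poisson",
    "assign_materials",
    "DEFAULT_TEST_MATERIAL",
]


def from_young_poisson(E: float, nu: float):
    """Convert (Young's modulus, Poisson ratio) to (shear, bulk) moduli.

    G = E / (2 (1 + nu)),  K = E / (3 (1 - 2 nu)).
    """
    if E <= 0:
        raise ValueError("Young's modulus must be positive")
    if not -1.0 < nu < 0.5:
        raise ValueError("Poisson ratio must lie in (-1, 0.5); the "
                         "incompressible limit nu = 0.5 is not supported")
    G = E / (2.0 * (1.0 + nu))
    K = E / (3.0 * (1.0 - 2.0 * nu))
    return G, K


def to_young_poisson(G: float, K: float):
    """Inverse of :func:`from_young_poisson`; involutive to roundoff."""
    if G <= 0 or K <= 0:
        raise ValueError("moduli must be positive")
    E = 9.0 * K * G / (3.0 * K + G)
    nu = (3.0 * K - 2.0 * G) / (2.0 * (3.0 * K + G))
    return E, nu


@dataclass(frozen=True)
class Material:
    """Isotropic Kelvin-Voigt material.

    Parameters
    ----------
    density : kg/m^3
    shear_modulus, bulk_modulus : Pa
    shear_viscosity, bulk_viscosity : Pa*s
        Internal Newtonian viscosities coupling to the strain rate.
    """

    density: float
    shear_modulus: float
    bulk_modulus: float
    shear_viscosity: float
    bulk_viscosity: float

    def __post_init__(self):
        if self.density <= 0:
            raise ValueError("density must be positive")
        if self.shear_modulus <= 0 or self.bulk_modulus <= 0:
            raise ValueError("elastic moduli must be positive")
        if self.shear_viscosity < 0 or self.bulk_viscosity < 0:
            raise ValueError("viscosities must be non-negative")
        # Derived Poisson ratio is automatically < 0.5 for finite K, G > 0.

    @classmethod
    def from_young_poisson(cls, density, E, nu, shear_viscosity, bulk_viscosity):
        G, K = from_young_poisson(E, nu)
        return cls(density, G, K, shear_viscosity, bulk_viscosity)

    @property
    def youngs_modulus(self) -> float:
        return to_young_poisson(self.shear_modulus, self.bulk_modulus)[0]

    @property
    def poisson_ratio(self) -> float:
        return to_young_poisson(self.shear_modulus, self.bulk_modulus)[1]


# rho = 1500 kg/m^3, E = 1 GPa, nu = 0.35, mu = 1e-3 Pa*s: the material of
# the sphere validation fixtures.
DEFAULT_TEST_MATERIAL = Material.from_young_poisson(
    1500.0, 1.0e9, 0.35, 1.0e-3, 1.0e-3
)


@dataclass(frozen=True)
class DragModel:
    """Local solvent drag applied at each node.

    Each node is treated as a sphere of effective radius ``node_radius`` (m)
    in a solvent of viscosity ``solvent_viscosity`` (Pa*s); its Stokes drag
    is 6 pi r mu.  ``solvent_viscosity = 0`` disables the external drag and
    its thermal noise.  ``temperature`` (K) sets k_B T for all noise terms.
    """

    solvent_viscosity: float = 0.0
    node_radius: float = 1.0e-9
    temperature: float = 300.0

    def __post_init__(self):
        if self.solvent_viscosity < 0:
            raise ValueError("solvent viscosity must be non-negative")
        if self.solvent_viscosity > 0 and self.node_radius <= 0:
            raise ValueError("node radius must be positive when drag is enabled")
        if self.temperature < 0:
            raise ValueError("temperature must be non-negative")

    @property
    def node_drag(self) -> float:
        """Stokes drag per node, kg/s."""
        return 6.0 * np.pi * self.node_radius * self.solvent_viscosity


class MaterialTable:
    """Constant-time per-element material lookup for a mesh."""

    def __init__(self, mesh, table):
        if isinstance(table, Material):
            table = {0: table}
        missing = sorted(set(np.unique(mesh.region_id)) - set(table))
        if missing:
            raise KeyError(
                f"mesh region id(s) {missing} have no material assigned"
            )
        self._regions = np.asarray(mesh.region_id)
        self._table = dict(table)
        ids = sorted(table)
        self._index = {r: i for i, r in enumerate(ids)}
        self._materials = [table[r] for r in ids]
        row = np.array([self._index[r] for r in self._regions], dtype=np.intp)
        self._per_element = np.array(
            [[m.density, m.shear_modulus, m.bulk_modulus,
              m.shear_viscosity, m.bulk_viscosity] for m in self._materials]
        )[row]
        self.homogeneous = len(ids) == 1

    def __getitem__(self, e: int) -> Material:
        return self._table[int(self._regions[e])]

    @property
    def density(self) -> np.ndarray:
        return self._per_element[:, 0]

    @property
    def shear_modulus(self) -> np.ndarray:
        return self._per_element[:, 1]

    @property
    def bulk_modulus(self) -> np.ndarray:
        return self._per_element[:, 2]

    @property
    def shear_viscosity(self) -> np.ndarray:
        return self._per_element[:, 3]

    @property
    def bulk_viscosity(self) -> np.ndarray:
        return self._per_element[:, 4]


def assign_materials(mesh, table) -> MaterialTable:
    """Bind a ``{region_id: Material}`` table (or one Material) to a mesh."""
    return MaterialTable(mesh, table)
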