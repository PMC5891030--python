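"""Normal modes and relaxation time-scales of a meshed sphere.

Linearises the elastic force about the reference shape, diagonalises the
stiffness matrix (generalised with the mass matrix) and prints the rigid
block, the softest elastic modes, and the two relaxation spectra that
bracket sensible simulation parameters: the slowest viscoelastic time
bounds how long a run must be to sample the softest mode, the fastest
inertial time bounds the stable explicit time-step.
"""

import numpy as np

from fluctfem.lem import normal_modes, rigid_mode_count, stiffness_matrix, timescales
from fluctfem.validation import sphere_model

model = sphere_model("coarse")
K = stiffness_matrix(model)
M = model.mass_matrix()
lam = model.viscosity_matrix()

eig = normal_modes(K, M, k=16)
print(f"rigid-body null modes: {rigid_mode_count(eig)} (expected 6)")
print("softest elastic eigenvalues (1/s^2, ascending):")
print(" ", np.array2string(eig.eigenvalues[6:16], precision=3))

tau_ve, tau_in = timescales(M, K, lam)
print(f"slowest viscoelastic relaxation: {tau_ve[-1]*1e12:.2f} ps "
      "(total run should cover many of these)")
print(f"fastest inertial relaxation:     {tau_in[0]*1e15:.2f} fs "
      "(explicit Langevin stepping needs dt below ~2x this)")
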