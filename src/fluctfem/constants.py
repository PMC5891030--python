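"""Physical constants and unit conversions.

All internal state is carried in SI units (metres, kilograms, seconds,
joules).  Mesh files and most user-facing parameters are expressed in
nanometres; the conversion happens exactly once, at load time.
"""

# Boltzmann constant, exact SI definition (J/K).
K_B = 1.380649e-23

# Length conversions.
NM = 1.0e-9       # nanometre in metres
ANGSTROM = 1.0e-10

# Time conversions.
NS = 1.0e-9
PS = 1.0e-12
FS = 1.0e-15


def nm_to_m(x):
    return x * NM


def m_to_nm(x):
    return x / NM
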