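"""Physical constants and element tables in the package's unit system.

Units everywhere: energies in eV, lengths in Angstrom, time in fs, masses
in amu (unified atomic mass units). All conversion factors derive from
scipy's CODATA values so the unit system is internally consistent.
"""

from __future__ import annotations

from scipy import constants as _c

#: Reduced Planck constant in eV*fs.
HBAR_EV_FS = _c.hbar / _c.e * 1e15  # 0.6582119569...

#: Boltzmann constant in eV/K.
KB_EV = _c.k / _c.e

#: 1 amu*Angstrom^2/fs^2 expressed in eV. Kinetic energy in eV is
#: 0.5 * m[amu] * v[A/fs]^2 * EV_PER_AMU_A2_FS2.
EV_PER_AMU_A2_FS2 = _c.atomic_mass * 1e-20 / 1e-30 / _c.e

#: hc in eV*nm, for the energy <-> wavelength axis conversion.
EV_NM = _c.h * _c.c / _c.e * 1e9  # 1239.84198...

#: Elements the potential supports, in canonical order.
SUPPORTED_ELEMENTS = ("H", "C", "N", "O", "F", "S", "Cl")

#: Standard atomic weights (amu), IUPAC 2021 conventional values.
ATOMIC_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998403163,
    "S": 32.06,
    "Cl": 35.45,
}

#: Single-bond covalent radii (Angstrom), Cordero et al. consensus values.
COVALENT_RADII = {
    "H": 0.31,
    "C": 0.76,
    "N": 0.71,
    "O": 0.66,
    "F": 0.57,
    "S": 1.05,
    "Cl": 1.02,
}
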