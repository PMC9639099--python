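"""Physical constants in the unit system used throughout the package.

Lengths are in Å, charges in units of the elementary charge e, energies in
kJ/mol, potentials in volts, concentrations in mol/L.  Everything here is
derived from CODATA values via :mod:`scipy.constants` rather than typed in,
so the numbers stay consistent with each other.
"""

import math

from scipy import constants as _c

#: Elementary charge, C.
ELEMENTARY_CHARGE = _c.e

#: Avogadro constant, 1/mol.
AVOGADRO = _c.N_A

#: Vacuum permittivity, F/m.
VACUUM_PERMITTIVITY = _c.epsilon_0

#: Boltzmann constant, J/K.
BOLTZMANN = _c.k

#: Molar gas constant, kJ/(mol K).
GAS_CONSTANT_KJ = _c.R / 1e3

#: Coulomb prefactor e^2/(4 pi eps0) scaled to kJ/mol for charges in e and
#: separations in Å (≈ 1389.35 kJ mol⁻¹ Å e⁻²).
COULOMB_KJ_MOL_ANGSTROM = (
    _c.e**2 * _c.N_A / (4.0 * math.pi * _c.epsilon_0) / 1e3 / 1e-10
)

#: Coulomb prefactor in volts for a unit charge at 1 Å (≈ 14.400 V Å e⁻¹).
COULOMB_VOLT_ANGSTROM = _c.e / (4.0 * math.pi * _c.epsilon_0) / 1e-10

#: Faraday constant scaled to kJ/mol per (e·V) (≈ 96.485).
FARADAY_KJ_MOL = _c.e * _c.N_A / 1e3

#: One debye in C·m.
DEBYE_SI = 1e-21 / _c.c

#: Conversion factor from e·Å to debye (≈ 4.803).
E_ANGSTROM_PER_DEBYE = _c.e * 1e-10 / DEBYE_SI

#: Thermal energy at 298.15 K, kJ/mol (≈ 2.479).
KT_ROOM_KJ_MOL = GAS_CONSTANT_KJ * 298.15
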