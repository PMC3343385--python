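"""Physical constants (CODATA 2018) and unit conversions.

All internal computation is in SI units.  User-facing quantities use the
conventions common in the electric-double-layer literature: concentrations
in mol/l, dipole moments in debye, surface charge densities in As/m^2
(identical to C/m^2).
"""

from __future__ import annotations

from typing import Final

#: Elementary charge, C.
E0: Final[float] = 1.602176634e-19
#: Vacuum permittivity, As/(V m).
EPS0: Final[float] = 8.8541878128e-12
#: Boltzmann constant, J/K.
KB: Final[float] = 1.380649e-23
#: Avogadro constant, 1/mol.
NA: Final[float] = 6.02214076e23
#: One debye in C m.
DEBYE: Final[float] = 3.33564095198152e-30


def mol_per_l_to_number_density(c_mol_l: float) -> float:
    """Convert a molar concentration (mol/l) to a number density (1/m^3)."""
    return c_mol_l * 1000.0 * NA


def number_density_to_mol_per_l(n_per_m3: float) -> float:
    """Convert a number density (1/m^3) to a molar concentration (mol/l)."""
    return n_per_m3 / (1000.0 * NA)


def debye_to_Cm(p_debye: float) -> float:
    """Convert a dipole moment in debye to C m."""
    return p_debye * DEBYE


def Cm_to_debye(p_Cm: float) -> float:
    """Convert a dipole moment in C m to debye."""
    return p_Cm / DEBYE
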