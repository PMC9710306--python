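"""Unit conventions and physical constants.

Internal units throughout the package: energies in Hartree, lengths in
angstrom, angles in degrees, time in femtoseconds, masses in unified atomic
mass units, temperature in kelvin.  User-facing reports use kcal/mol.
"""

from scipy import constants as _c

#: Hartree -> kcal/mol (fixed reporting conversion).
HARTREE_TO_KCAL = 627.509474

#: Boltzmann constant in Hartree/K.
KB_HARTREE = _c.k / _c.physical_constants["Hartree energy"][0]

#: Conversion for Newton's second law in internal units:
#: acceleration [A/fs^2] = (force [Hartree/A] / mass [amu]) * ACCEL_FACTOR.
#: Equivalently Hartree/(amu) expressed in (A/fs)^2.
ACCEL_FACTOR = (
    _c.physical_constants["Hartree energy"][0]
    / _c.atomic_mass
    * 1e-10  # m^2/s^2 -> A^2/fs^2  (1e20 / 1e30)
)

#: Planck constant, speed of light (SI) for rotational constants.
PLANCK = _c.h
C_LIGHT_CM = _c.c * 100.0  # cm/s
AMU_KG = _c.atomic_mass
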