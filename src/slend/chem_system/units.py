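"""Physical constants and unit conversion.

Internal units throughout the package are Hartree atomic units: length in
Bohr, time in a.u. (1 a.u. = 2.41888425e-2 fs), energy in Hartree, mass in
electron masses.  User-facing I/O happens in Angstrom / fs / keV with
explicit conversion at the boundaries.
"""

from __future__ import annotations

import math

#: 1 atomic unit of time in femtoseconds.
AU_TIME_FS = 2.41888425e-2
#: 1 Hartree in electronvolt (CODATA 2018).
HARTREE_EV = 27.211386245988
#: 1 Bohr in Angstrom (CODATA 2018).
BOHR_ANGSTROM = 0.529177210903
#: Bare proton mass in electron masses (CODATA 2018).
PROTON_MASS_AU = 1836.15267343
#: 1 unified atomic mass unit in electron masses (CODATA 2018).
AMU_TO_ME = 1822.888486209


class DimensionError(ValueError):
    """Raised when a conversion mixes units of different dimensions."""


# Registered conversion factors: value of 1 <unit> expressed in the base
# unit of its dimension (base units: a.u. time, Hartree, Bohr, m_e).
_REGISTRY: dict[str, dict[str, float]] = {
    "time": {"au": 1.0, "fs": 1.0 / AU_TIME_FS},
    "energy": {
        "hartree": 1.0,
        "ev": 1.0 / HARTREE_EV,
        "kev": 1000.0 / HARTREE_EV,
    },
    "length": {"bohr": 1.0, "angstrom": 1.0 / BOHR_ANGSTROM},
    "mass": {"me": 1.0, "amu": AMU_TO_ME, "proton": PROTON_MASS_AU},
}

_UNIT_DIMENSION = {
    unit: dim for dim, units in _REGISTRY.items() for unit in units
}


class UnitRegistry:
    """Lookup table of conversion factors between units of one dimension.

    ``convert`` is an exact multiplication by the ratio of registered
    factors, so round trips reproduce the input to floating-point accuracy.
    """

    def __init__(self) -> None:
        self._registry = _REGISTRY

    def dimension_of(self, unit: str) -> str:
        try:
            return _UNIT_DIMENSION[unit.lower()]
        except KeyError:
            raise DimensionError(f"unknown unit {unit!r}") from None

    def convert(self, value: float, from_unit: str, to_unit: str) -> float:
        """Convert ``value`` from one registered unit to another."""
        fdim = self.dimension_of(from_unit)
        tdim = self.dimension_of(to_unit)
        if fdim != tdim:
            raise DimensionError(
                f"cannot convert {from_unit!r} ({fdim}) to {to_unit!r} ({tdim})"
            )
        table = self._registry[fdim]
        return value * (table[from_unit.lower()] / table[to_unit.lower()])


#: Module-level registry shared by the package.
units = UnitRegistry()


def convert(value: float, from_unit: str, to_unit: str) -> float:
    """Convert a scalar between registered units (see :class:`UnitRegistry`)."""
    return units.convert(value, from_unit, to_unit)


def projectile_speed(kinetic_energy_kev: float, mass_au: float) -> float:
    """Nonrelativistic speed (a.u.) of a projectile of given kinetic energy.

    v = sqrt(2 E / m) with E converted from keV to Hartree.  A 100 keV
    proton moves at about 2.0008 a.u.; relativistic corrections at these
    energies are below 0.03% and are neglected.
    """
    if kinetic_energy_kev < 0:
        raise ValueError("kinetic energy must be non-negative")
    if mass_au <= 0:
        raise ValueError("mass must be positive")
    e_hartree = convert(kinetic_energy_kev, "kev", "hartree")
    return math.sqrt(2.0 * e_hartree / mass_au)
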