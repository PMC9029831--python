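"""Unit tags and conversions.

Internal units throughout the package are kcal/mol for energies, Å for
lengths, radians for angles entering energy expressions, and ps for time.
SI values (newton, newton-metre) appear only at I/O boundaries, e.g. when
mean forces logged by an MD engine are imported.

The single physical constant used is the per-entity value of the thermal
calorie: 1 kcal/mol = 6.947695e-21 J.
"""

from __future__ import annotations

import math

from .errors import UnitError

#: 1 kcal/mol expressed in joule per entity.
KCAL_PER_MOL_IN_J = 6.947695e-21

#: 1 Å in metres.
ANGSTROM_IN_M = 1e-10

# Each tag maps to (dimension, factor) where ``factor`` converts a value in
# that unit into the dimension's internal unit (first alias listed below).
_UNIT_TABLE: dict[str, tuple[str, float]] = {}


def _register(dimension: str, factor: float, *aliases: str) -> None:
    for alias in aliases:
        _UNIT_TABLE[alias.lower()] = (dimension, factor)


# force: internal kcal/mol/Å
_register("force", 1.0, "kcal/mol/A", "kcal/mol/angstrom", "kcal/mol/Å")
_register("force", ANGSTROM_IN_M / KCAL_PER_MOL_IN_J, "N", "newton")
# torque: internal kcal/mol/rad
_register("torque", 1.0, "kcal/mol/rad")
_register("torque", 1.0 / KCAL_PER_MOL_IN_J, "N*m", "Nm", "newton-metre", "newton-meter")
_register("torque", 180.0 / math.pi, "kcal/mol/deg")
# energy: internal kcal/mol
_register("energy", 1.0, "kcal/mol")
_register("energy", 1.0 / KCAL_PER_MOL_IN_J, "J", "joule")
# temperature (identity only; offsets are out of scope)
_register("temperature", 1.0, "K", "kelvin")
# diffusion: internal Å^2/ps; note 1 Å^2/ps = 1e-8 m^2/s exactly
_register("diffusion", 1.0, "A^2/ps", "angstrom^2/ps", "Å^2/ps")
_register("diffusion", 1e8, "m^2/s")
_register("diffusion", 1.0, "1e-8 m^2/s")
# time: internal ps
_register("time", 1.0, "ps")
_register("time", 1e-3, "fs")
_register("time", 1e3, "ns")
# length: internal Å
_register("length", 1.0, "A", "angstrom", "Å")
_register("length", 1.0 / ANGSTROM_IN_M, "m")
_register("length", 10.0, "nm")


def _lookup(tag: str) -> tuple[str, float]:
    try:
        return _UNIT_TABLE[tag.lower()]
    except KeyError:
        raise UnitError(f"unknown unit tag {tag!r}") from None


def dimension_of(tag: str) -> str:
    """Return the dimension name ('force', 'torque', ...) of a unit tag."""
    return _lookup(tag)[0]


def convert_units(value: float, from_unit: str, to_unit: str) -> float:
    """Convert ``value`` between dimensionally compatible unit tags.

    Conversions are exact multiplications, so A -> B -> A round-trips to
    within 1e-12 relative.

    Raises
    ------
    UnitError
        If either tag is unknown or the dimensions differ.
    """
    dim_from, f_from = _lookup(from_unit)
    dim_to, f_to = _lookup(to_unit)
    if dim_from != dim_to:
        raise UnitError(
            f"incompatible dimensions: {from_unit!r} is {dim_from}, {to_unit!r} is {dim_to}"
        )
    return value * (f_from / f_to)
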