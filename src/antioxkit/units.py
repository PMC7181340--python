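"""Energy unit conversions and report rounding.

Single source of truth for the physical constants used across the package.
Quantum-chemistry outputs arrive in hartree; antioxidant thermochemistry is
conventionally reported in kcal/mol and orbital energies in eV, so every
module converts through the constants defined here rather than carrying its
own copies.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

#: kcal/mol per hartree
HARTREE_TO_KCAL = 627.5095
#: eV per hartree
HARTREE_TO_EV = 27.2114
#: photon energy–wavelength product, eV·nm (hc)
EV_NM_PRODUCT = 1239.842

#: conversion factors to hartree, keyed by unit name
_TO_HARTREE = {
    "hartree": 1.0,
    "kcal/mol": 1.0 / HARTREE_TO_KCAL,
    "eV": 1.0 / HARTREE_TO_EV,
}

KNOWN_UNITS = frozenset(_TO_HARTREE)


class UnknownUnitError(ValueError):
    """Raised when an energy unit name is not recognised."""


def convert_energy(value: float, from_unit: str, to_unit: str) -> float:
    """Convert an energy between hartree, kcal/mol and eV.

    Conversion is linear through hartree; identical units return the value
    unchanged (no round-trip error).
    """
    if from_unit not in _TO_HARTREE:
        raise UnknownUnitError(f"unknown energy unit: {from_unit!r}")
    if to_unit not in _TO_HARTREE:
        raise UnknownUnitError(f"unknown energy unit: {to_unit!r}")
    if from_unit == to_unit:
        return value
    return value * _TO_HARTREE[from_unit] / _TO_HARTREE[to_unit]


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Round with ties away from zero, as in hand-rounded tables.

    Python's builtin ``round`` uses banker's rounding; printed chemistry
    tables round 0.005 up, so reports go through this helper. Rounding
    happens only at the report boundary — engines keep full precision.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))
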