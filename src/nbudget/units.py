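"""Nitrogen mass units.

All internal bookkeeping is done in grams of N stored as a plain float;
power-of-ten SI prefixes (kg, Mg = tonne, Gg = kilotonne) are the display
and reporting units.  Conversion is exact multiplication by powers of ten,
so round-trips are lossless to floating-point precision.
"""

from __future__ import annotations

from dataclasses import dataclass

GRAMS_PER_UNIT: dict[str, float] = {
    "g": 1.0,
    "kg": 1e3,
    "Mg": 1e6,
    "Gg": 1e9,
}

_UNIT_ORDER = ["Gg", "Mg", "kg", "g"]


def to_grams(value: float, unit: str) -> float:
    """Convert *value* expressed in *unit* to grams."""
    try:
        return value * GRAMS_PER_UNIT[unit]
    except KeyError:
        raise ValueError(f"unknown mass unit {unit!r}; expected one of {sorted(GRAMS_PER_UNIT)}")


def from_grams(grams: float, unit: str) -> float:
    """Convert a gram amount to *unit*."""
    try:
        return grams / GRAMS_PER_UNIT[unit]
    except KeyError:
        raise ValueError(f"unknown mass unit {unit!r}; expected one of {sorted(GRAMS_PER_UNIT)}")


def convert(value: float, from_unit: str, to_unit: str) -> float:
    return from_grams(to_grams(value, from_unit), to_unit)


@dataclass(frozen=True)
class NMass:
    """A nitrogen mass, canonically held in grams.

    Supports addition/subtraction with other :class:`NMass` and scaling by
    scalars, so linear accounting identities read naturally.
    """

    grams: float

    @classmethod
    def of(cls, value: float, unit: str = "g") -> "NMass":
        return cls(to_grams(value, unit))

    def to(self, unit: str) -> float:
        return from_grams(self.grams, unit)

    def __add__(self, other: "NMass") -> "NMass":
        return NMass(self.grams + other.grams)

    def __sub__(self, other: "NMass") -> "NMass":
        return NMass(self.grams - other.grams)

    def __mul__(self, factor: float) -> "NMass":
        return NMass(self.grams * factor)

    __rmul__ = __mul__

    def __neg__(self) -> "NMass":
        return NMass(-self.grams)

    def __str__(self) -> str:
        return format_grams(self.grams)


def format_grams(grams: float, sig: int = 3) -> str:
    """Render a gram amount with the largest prefix giving magnitude >= 1.

    Three significant digits by default, matching the typical precision of
    reported national N flows.
    """
    mag = abs(grams)
    for unit in _UNIT_ORDER:
        if mag >= GRAMS_PER_UNIT[unit]:
            break
    else:
        unit = "g"
    value = from_grams(grams, unit)
    return f"{value:.{sig}g} {unit} N"
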