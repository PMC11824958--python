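"""Item-quantity to nitrogen-mass conversion rules and the coefficient registry.

Every commodity handled by the budget is converted to nitrogen mass by one
of a small set of linear rules:

``mass-N-direct``
    the reported quantity already is N (synthetic fertilizer statistics);
``mass-protein``
    gravimetric quantity x protein fraction / 6.25 (Jones' factor),
    uplifted by 15 % for non-protein N (nucleic acids etc.);
``mass-fresh``
    fisheries fresh weight: usable fraction 0.75, then the item's N
    fraction of usable weight;
``volume-wood``
    volumetric wood: basic density (dry kg per green m3) x dry-wood N
    fraction;
``mass-fossil``
    gravimetric fossil fuel x N fraction, with the metallurgical-coke
    special case (2 % when accounting production, 0 % in trade);
``mass-fraction``
    plain gravimetric quantity x N fraction (pulp and paper, both 0).

All rules are linear and vanish at zero, which the accounting relies on:
converting a sum equals summing conversions.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Dict, Optional

# --- protein chemistry -----------------------------------------------------

#: Jones' factor: grams of protein per gram of protein N.
JONES_FACTOR = 6.25
#: Uplift for non-protein N in food items (nucleic acids and other organics).
NON_PROTEIN_N_UPLIFT = 1.15

# --- live animals ----------------------------------------------------------

DRESSED_WEIGHT_FACTOR = 0.7     # carcass / live weight
PROTEIN_PER_MEAT = 0.18         # protein weight / meat weight
N_PER_PROTEIN = 0.16            # 1 / Jones' factor
#: Combined live weight -> N factor, 0.7 * 0.18 * 0.16.
LIVE_WEIGHT_TO_N = DRESSED_WEIGHT_FACTOR * PROTEIN_PER_MEAT * N_PER_PROTEIN

#: Default live weights (kg) per traded animal species.
ANIMAL_LIVE_WEIGHT_KG: Dict[str, float] = {
    "ass": 125.0,
    "cattle": 175.0,
    "buffalo": 175.0,
    "chicken": 2.5,
    "horse": 200.0,
    "mule": 175.0,
    "sheep": 25.0,
    "goat": 25.0,
    "turkey": 7.5,
}

# --- wood ------------------------------------------------------------------

WOOD_BASIC_DENSITY_KG_M3 = {"conifer": 400.0, "nonconifer": 500.0, "pulp": 400.0}
WOOD_N_FRACTION = {"conifer": 0.0014, "nonconifer": 0.0017, "pulp": 0.0}

# --- fossil fuels ----------------------------------------------------------

FOSSIL_N_FRACTION = {"petroleum": 0.004, "coal-bituminous": 0.020, "coke": 0.020}

# --- fisheries -------------------------------------------------------------

#: Usable fraction of caught fresh body weight.
FISH_USABLE_FRACTION = 0.75


@dataclass(frozen=True)
class EmissionFactors:
    """N fractions for airborne emissions.

    NOx is treated as 95 % NO / 5 % NO2.  Two modes exist for converting an
    emitted NOx or NH3 mass to N mass: the reporting constants used in the
    national accounts (0.44 for NOx, 0.82 for NH3), and the stoichiometric
    mixture values (0.95*14/30 + 0.05*14/46 for NOx, 14/17 for NH3).  The
    per-person breath/skin ammonia pathway uses 0.833 as its N/NH3 factor.
    """

    f_no: float = 0.95
    f_no2: float = 0.05
    r_no: float = 14.0 / 30.0
    r_no2: float = 14.0 / 46.0
    n_fraction_nox_reporting: float = 0.44
    n_fraction_nh3_reporting: float = 0.82
    n_fraction_nh3_people: float = 0.833

    @property
    def n_fraction_nox_stoichiometric(self) -> float:
        return self.f_no * self.r_no + self.f_no2 * self.r_no2

    @property
    def n_fraction_nh3_stoichiometric(self) -> float:
        return 14.0 / 17.0


EMISSION_FACTORS = EmissionFactors()

_BASES = {"mass-N-direct", "mass-protein", "mass-fresh",
          "volume-wood", "mass-fossil", "mass-fraction"}


@dataclass(frozen=True)
class NItem:
    """One registry entry: a commodity and its N-derivation rule."""

    name: str
    category: str
    basis: str
    protein_fraction: Optional[float] = None
    n_fraction: Optional[float] = None
    density_kg_per_m3: Optional[float] = None
    note: str = ""

    def __post_init__(self):
        if self.basis not in _BASES:
            raise ValueError(f"{self.name}: unknown basis {self.basis!r}")
        if self.basis == "mass-protein" and self.protein_fraction is None:
            raise ValueError(f"{self.name}: mass-protein basis requires protein_fraction")
        if self.basis in ("mass-fresh", "mass-fossil", "mass-fraction") and self.n_fraction is None:
            raise ValueError(f"{self.name}: basis {self.basis} requires n_fraction")
        if self.basis == "volume-wood" and (self.n_fraction is None or self.density_kg_per_m3 is None):
            raise ValueError(f"{self.name}: volume-wood basis requires n_fraction and density")


# --- scalar converters -----------------------------------------------------


def _require_nonneg(x: float, what: str) -> None:
    if x < 0 or not math.isfinite(x):
        raise ValueError(f"{what} must be finite and non-negative, got {x}")


def protein_to_nitrogen(protein_mass: float) -> float:
    """Protein mass -> N mass via Jones' factor (divide by 6.25)."""
    _require_nonneg(protein_mass, "protein mass")
    return protein_mass / JONES_FACTOR


def food_item_nitrogen(item: NItem, mass: float, uplift: float = NON_PROTEIN_N_UPLIFT) -> float:
    """N in a food/feed item from its protein fraction, incl. non-protein N."""
    _require_nonneg(mass, "mass")
    if item.protein_fraction is None:
        raise ValueError(f"{item.name}: protein_fraction missing")
    return mass * item.protein_fraction / JONES_FACTOR * uplift


def live_animal_nitrogen(live_mass: float) -> float:
    """N contained in an animal (or person) from its live weight.

    Dressed weight (0.7) x protein per meat (0.18) x N per protein (0.16).
    """
    _require_nonneg(live_mass, "live mass")
    return live_mass * LIVE_WEIGHT_TO_N


def wood_nitrogen(volume_m3: float, kind: str) -> float:
    """N (kg) in *volume_m3* of roundwood of the given kind.

    Conifer: 400 kg/m3 dry at 0.14 % N; non-conifer: 500 kg/m3 at 0.17 %;
    pulp carries no N (removed during pulping).
    """
    _require_nonneg(volume_m3, "volume")
    try:
        return volume_m3 * WOOD_BASIC_DENSITY_KG_M3[kind] * WOOD_N_FRACTION[kind]
    except KeyError:
        raise ValueError(f"unknown wood kind {kind!r}; expected one of {sorted(WOOD_N_FRACTION)}")


def fossil_fuel_nitrogen(fuel: str, mass: float, flow: str = "production") -> float:
    """N in a fossil-fuel mass.

    Petroleum 0.4 %, bituminous coal 2.0 %.  Metallurgical coke counts 2 %
    when produced (it is made from bituminous coal, whose N is then lost in
    coking) but 0 % in trade (the out-gassing removes N before shipping).
    """
    _require_nonneg(mass, "mass")
    if fuel not in FOSSIL_N_FRACTION:
        raise ValueError(f"unknown fuel {fuel!r}; expected one of {sorted(FOSSIL_N_FRACTION)}")
    if fuel == "coke" and flow != "production":
        return 0.0
    return mass * FOSSIL_N_FRACTION[fuel]


def nox_nitrogen_mass(m_nox: float, mode: str = "reporting",
                      factors: EmissionFactors = EMISSION_FACTORS) -> float:
    """N mass in an emitted NOx mass (reporting constant or stoichiometric)."""
    _require_nonneg(m_nox, "NOx mass")
    if mode == "reporting":
        return m_nox * factors.n_fraction_nox_reporting
    if mode == "stoichiometric":
        return m_nox * factors.n_fraction_nox_stoichiometric
    raise ValueError(f"unknown mode {mode!r}")


def nh3_nitrogen_mass(m_nh3: float, mode: str = "reporting",
                      factors: EmissionFactors = EMISSION_FACTORS) -> float:
    """N mass in an emitted NH3 mass (reporting constant or stoichiometric)."""
    _require_nonneg(m_nh3, "NH3 mass")
    if mode == "reporting":
        return m_nh3 * factors.n_fraction_nh3_reporting
    if mode == "stoichiometric":
        return m_nh3 * factors.n_fraction_nh3_stoichiometric
    raise ValueError(f"unknown mode {mode!r}")


# --- registry --------------------------------------------------------------


def item_nitrogen(item: NItem, quantity: float, flow: str = "production") -> float:
    """Apply an item's conversion rule.

    *quantity* is grams for mass bases and m3 for ``volume-wood``; the
    return value is grams of N in both cases.
    """
    _require_nonneg(quantity, f"{item.name} quantity")
    if item.basis == "mass-N-direct":
        return quantity * (item.n_fraction if item.n_fraction is not None else 1.0)
    if item.basis == "mass-protein":
        return food_item_nitrogen(item, quantity)
    if item.basis == "mass-fresh":
        return quantity * FISH_USABLE_FRACTION * item.n_fraction
    if item.basis == "volume-wood":
        # density is kg/m3, N fraction on dry weight -> kg N, then grams
        return quantity * item.density_kg_per_m3 * item.n_fraction * 1e3
    if item.basis == "mass-fossil":
        if item.category == "coke" and flow != "production":
            return 0.0
        return quantity * item.n_fraction
    if item.basis == "mass-fraction":
        return quantity * item.n_fraction
    raise AssertionError(f"unhandled basis {item.basis}")


def _opt_float(s: str) -> Optional[float]:
    s = s.strip()
    return float(s) if s else None


def load_registry(path: Optional[str | Path] = None) -> Dict[str, NItem]:
    """Load the coefficient registry CSV into a name -> NItem mapping.

    Columns: item, category, basis, protein_fraction, n_fraction,
    density_kg_per_m3, note.  Unknown items looked up later fail loudly
    rather than defaulting.
    """
    if path is None:
        source = resources.files("nbudget.data").joinpath("coefficients.csv")
        text = source.read_text(encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    registry: Dict[str, NItem] = {}
    reader = csv.DictReader(text.splitlines())
    required = {"item", "category", "basis"}
    if reader.fieldnames is None or not required.issubset(reader.fieldnames):
        raise ValueError(f"registry must have columns {sorted(required)}")
    for row in reader:
        item = NItem(
            name=row["item"].strip(),
            category=row["category"].strip(),
            basis=row["basis"].strip(),
            protein_fraction=_opt_float(row.get("protein_fraction", "") or ""),
            n_fraction=_opt_float(row.get("n_fraction", "") or ""),
            density_kg_per_m3=_opt_float(row.get("density_kg_per_m3", "") or ""),
            note=(row.get("note") or "").strip(),
        )
        if item.name in registry:
            raise ValueError(f"duplicate registry item {item.name!r}")
        registry[item.name] = item
    return registry
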