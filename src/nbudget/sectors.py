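"""Per-sector nitrogen-flow computations.

Each function computes one sector-level quantity of the national budget:
manure retention, aquaculture and livestock feed-conversion efficiencies,
per-capita protein supply, migration and breath/skin N of the population,
sewage-sludge and biowaste N, airborne-emission N, and the generic
commodity-table -> N-account conversion.

Unless a docstring says otherwise, masses passed in and returned are grams
of N (scalar converters are linear, so any consistent unit works for the
pure ratios).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

import pandas as pd

from . import ncontent
from .ncontent import NItem
from .series import AnnualSeries

HOURS_PER_YEAR = 8760.0

#: Directions a sector flow can take within an account.
DIRECTIONS = ("production", "import", "export", "domestic_supply",
              "loss_to_water", "loss_to_air", "applied_to_soil", "retained")


@dataclass(frozen=True)
class SectorFlow:
    label: str
    direction: str
    n_grams: float

    def __post_init__(self):
        if self.direction not in DIRECTIONS:
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.n_grams < 0 or not math.isfinite(self.n_grams):
            raise ValueError(f"{self.label}: flow mass must be finite and >= 0")


@dataclass
class SectorAccount:
    """N flows of one sector in one year."""

    sector: str
    year: int
    flows: List[SectorFlow] = field(default_factory=list)
    notes: str = ""

    def add(self, label: str, direction: str, n_grams: float) -> None:
        if any(f.label == label for f in self.flows):
            raise ValueError(f"duplicate flow label {label!r} in {self.sector}/{self.year}")
        self.flows.append(SectorFlow(label, direction, n_grams))

    def total(self, direction: str) -> float:
        return sum(f.n_grams for f in self.flows if f.direction == direction)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"sector": self.sector, "year": self.year, "label": f.label,
              "direction": f.direction, "n_gg": f.n_grams / 1e9}
             for f in self.flows]
        )


# --- livestock manure ------------------------------------------------------


@dataclass
class ManureAccount:
    """Excreted/left/applied manure N and its losses for one year.

    Base amounts: ``n_excreted`` (total excretion), ``n_pasture`` (left on
    pasture), ``n_applied`` (collected, treated and applied to soils), each
    with leached and volatilized components.  Amounts share one unit
    (conventionally Gg N yr-1).  Derived fields are filled by
    :func:`manure_retention`.
    """

    year: int
    n_excreted: float
    n_pasture: float
    n_applied: float
    n_pasture_leached: float = 0.0
    n_pasture_volatile: float = 0.0
    n_applied_leached: float = 0.0
    n_applied_volatile: float = 0.0
    n_retained: Optional[float] = None
    n_loss: Optional[float] = None
    pct_retained: Optional[float] = None

    @classmethod
    def from_totals(cls, year: int, n_excreted: float, n_pasture: float, n_applied: float,
                    leached_total: float, volatile_total: float) -> "ManureAccount":
        """Build an account when only total leaching/volatilization is known.

        The totals are allocated pro-rata to the pasture-left and applied
        amounts.
        """
        base = n_pasture + n_applied
        if base <= 0:
            raise ValueError("pasture + applied manure must be positive to allocate losses")
        wp = n_pasture / base
        return cls(
            year=year, n_excreted=n_excreted, n_pasture=n_pasture, n_applied=n_applied,
            n_pasture_leached=leached_total * wp,
            n_pasture_volatile=volatile_total * wp,
            n_applied_leached=leached_total * (1 - wp),
            n_applied_volatile=volatile_total * (1 - wp),
        )


def manure_retention(acc: ManureAccount) -> ManureAccount:
    """Fill the derived retention fields of a manure account.

    retained = (pasture - its losses) + (applied - its losses);
    loss = excreted - retained;  pct = retained / excreted x 100.
    """
    for name in ("n_excreted", "n_pasture", "n_applied", "n_pasture_leached",
                 "n_pasture_volatile", "n_applied_leached", "n_applied_volatile"):
        if getattr(acc, name) < 0:
            raise ValueError(f"{name} must be non-negative")
    if acc.n_excreted == 0 and (acc.n_pasture or acc.n_applied):
        raise ValueError("zero excretion with nonzero manure components")
    retained = ((acc.n_pasture - acc.n_pasture_leached - acc.n_pasture_volatile)
                + (acc.n_applied - acc.n_applied_leached - acc.n_applied_volatile))
    loss = acc.n_excreted - retained
    pct = retained / acc.n_excreted * 100.0 if acc.n_excreted else 0.0
    return replace(acc, n_retained=retained, n_loss=loss, pct_retained=pct)


# --- efficiency ratios -----------------------------------------------------


def aquaculture_retention(n_in_fish: float, n_in_feed: float) -> float:
    """Fraction of feed N retained in aquaculture products."""
    if n_in_feed <= 0:
        raise ValueError("feed N must be positive")
    if n_in_fish < 0:
        raise ValueError("fish N must be non-negative")
    return n_in_fish / n_in_feed


def livestock_conversion_rate(n_in_products: float,
                              feed_components: Iterable[float] | float) -> float:
    """Retained product N over aggregate feed N.

    *feed_components* is either the feed total or an iterable of the feed
    sources (food-category feed, imported feed, non-food feed, forage).
    """
    total = (float(feed_components) if isinstance(feed_components, (int, float))
             else sum(feed_components))
    if total <= 0:
        raise ValueError("total feed N must be positive")
    if n_in_products < 0:
        raise ValueError("product N must be non-negative")
    return n_in_products / total


# --- people ----------------------------------------------------------------


def per_capita_protein_supply(total_protein_g_per_year: float, population: int) -> float:
    """Protein supply in g person-1 day-1."""
    if population <= 0:
        raise ValueError("population must be positive")
    if total_protein_g_per_year < 0:
        raise ValueError("protein supply must be non-negative")
    return total_protein_g_per_year / population / 365.0


def people_breath_skin_emission(population: int,
                                rate_mg_per_person_hour: float = 0.8,
                                nh3_n_fraction: float = ncontent.EMISSION_FACTORS.n_fraction_nh3_people,
                                ) -> float:
    """Yearly N (grams) emitted as ammonia through skin and breath.

    0.8 mg NH3 per adult per hour, times the N fraction of ammonia, the
    population, and 8760 hours per year.
    """
    if population < 0:
        raise ValueError("population must be non-negative")
    if rate_mg_per_person_hour < 0:
        raise ValueError("emission rate must be non-negative")
    return rate_mg_per_person_hour * 1e-3 * nh3_n_fraction * population * HOURS_PER_YEAR


def migration_nitrogen(net_people: int, mean_live_weight_kg: float = 75.0) -> float:
    """Signed N (grams) carried by net migration.

    Uses the live-weight -> N chain (0.7 x 0.18 x 0.16) applied to the mean
    body weight; negative for net emigration.
    """
    per_person_g = ncontent.live_animal_nitrogen(mean_live_weight_kg * 1e3)
    return net_people * per_person_g


# --- sewage and waste ------------------------------------------------------


def sludge_nitrogen(dry_sludge_grams: float, n_fraction: float = 0.025) -> float:
    """N (grams) in dry sewage sludge at the given N content."""
    if not 0.0 <= n_fraction <= 1.0:
        raise ValueError("n_fraction must lie in [0, 1]")
    if dry_sludge_grams < 0:
        raise ValueError("sludge mass must be non-negative")
    return dry_sludge_grams * n_fraction


def sewage_per_capita(national_loss_g_per_year: float, population: int) -> Tuple[float, float]:
    """Sewage N loss per person: (kg person-1 yr-1, g person-1 day-1)."""
    if population <= 0:
        raise ValueError("population must be positive")
    if national_loss_g_per_year < 0:
        raise ValueError("loss must be non-negative")
    yearly_kg = national_loss_g_per_year / population / 1e3
    return yearly_kg, yearly_kg * 1e3 / 365.0


def biowaste_nitrogen(component_masses_kt: Mapping[str, float],
                      mixed_waste_kt: float = 0.0,
                      mixed_waste_share: float = 0.5,
                      n_g_per_kg: float = 9.5) -> float:
    """N (grams) in consolidated biowaste.

    Fully-counted components (wet-organic, park/garden, wood waste, rubber)
    enter whole; mixed household waste enters with *mixed_waste_share*
    (default half, the bio fraction).  All masses in kilotonnes; the
    consolidated mass carries ``n_g_per_kg`` grams of N per kg.
    """
    if not 0.0 <= mixed_waste_share <= 1.0:
        raise ValueError("mixed_waste_share must lie in [0, 1]")
    if mixed_waste_kt < 0 or any(v < 0 for v in component_masses_kt.values()):
        raise ValueError("waste masses must be non-negative")
    total_kt = sum(component_masses_kt.values()) + mixed_waste_share * mixed_waste_kt
    return total_kt * 1e6 * n_g_per_kg  # kt -> kg, then g N per kg


# --- airborne emissions ----------------------------------------------------


def emissions_account(nox_by_sector_g: Mapping[str, float],
                      nh3_by_sector_g: Mapping[str, float],
                      year: int,
                      mode: str = "reporting") -> SectorAccount:
    """Convert per-sector NOx and NH3 emission masses (grams) to an N account."""
    acc = SectorAccount(sector="emissions", year=year,
                        notes=f"NOx/NH3 converted with mode={mode}")
    for name, mass in nox_by_sector_g.items():
        acc.add(f"NOx {name}", "loss_to_air", ncontent.nox_nitrogen_mass(mass, mode))
    for name, mass in nh3_by_sector_g.items():
        acc.add(f"NH3 {name}", "loss_to_air", ncontent.nh3_nitrogen_mass(mass, mode))
    return acc


# --- commodity tables ------------------------------------------------------

_MASS_UNIT_GRAMS = {
    "g": 1.0, "kg": 1e3, "t": 1e6, "tonnes": 1e6, "tonne": 1e6,
    "1000 t": 1e9, "kt": 1e9, "gg": 1e9,
}
_VOLUME_UNIT_M3 = {"m3": 1.0, "1000 m3": 1e3, "mm3": 1e6}


def _quantity_to_base(value: float, unit: str, item: NItem) -> float:
    """Normalize a table quantity to grams (mass bases) or m3 (wood)."""
    key = unit.strip().lower()
    if item.basis == "volume-wood":
        if key not in _VOLUME_UNIT_M3:
            raise ValueError(f"{item.name}: expected a volume unit, got {unit!r}")
        return value * _VOLUME_UNIT_M3[key]
    if key not in _MASS_UNIT_GRAMS:
        raise ValueError(f"{item.name}: unknown mass unit {unit!r}")
    return value * _MASS_UNIT_GRAMS[key]


def commodity_sector_account(tables: Iterable[AnnualSeries],
                             registry: Mapping[str, NItem],
                             sector: str) -> Dict[int, SectorAccount]:
    """Convert a collection of annual series into per-year sector accounts.

    Every series item must resolve in the registry (unresolvable items are
    reported together in one error).  Per year and direction, item
    quantities are converted to N and summed per item label.
    """
    tables = list(tables)
    unresolved = sorted({s.item for s in tables if s.item not in registry})
    if unresolved:
        raise KeyError(f"items missing from registry: {unresolved}")
    accounts: Dict[int, SectorAccount] = {}
    for s in tables:
        item = registry[s.item]
        direction = s.element if s.element in DIRECTIONS else "domestic_supply"
        for year, value in sorted(s.values.items()):
            base = _quantity_to_base(value, s.unit, item)
            n_g = ncontent.item_nitrogen(item, base, flow=direction)
            acc = accounts.setdefault(year, SectorAccount(sector=sector, year=year))
            acc.add(f"{s.item} ({s.element})", direction, n_g)
    return accounts


def accounts_to_frame(accounts: Mapping[int, SectorAccount]) -> pd.DataFrame:
    """Tidy (sector, year, label, direction, n_gg) frame over all years."""
    frames = [accounts[y].to_frame() for y in sorted(accounts)]
    if not frames:
        return pd.DataFrame(columns=["sector", "year", "label", "direction", "n_gg"])
    return pd.concat(frames, ignore_index=True)
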