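"""Synthetic input generation with closed-form ground truth.

The national statistics the budget consumes (commodity tables in the
FAO long dialect, a coefficient registry, a categorical biome raster) are
emulated here so every pipeline stage is testable without downloads.  Each
scenario is generated from an integer seed and is bit-reproducible; the
generator emits, alongside the raw tables, the ground-truth N flows
computed in closed form from the ungapped series, so end-to-end recovery
can be asserted rather than eyeballed.

Quantity trends are piecewise linear by default, which makes
interpolation-based gap repair exact and keeps recovery tests sharp; a
curved (quadratic) option and additive noise exist for robustness testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from . import ncontent, sectors
from .biomes import RasterGrid
from .budget import FlowNetwork
from .ncontent import NItem
from .series import DEFAULT_HORIZON, AnnualSeries, fill_series

#: FAO-dialect element labels, keyed by the internal direction names.
FAO_ELEMENTS = {
    "production": "Production",
    "import": "Import quantity",
    "export": "Export quantity",
    "domestic_supply": "Domestic supply quantity",
}

#: Feed-N retention of farmed fish, used to size the synthetic feed flow.
AQUACULTURE_RETENTION = 0.33


@dataclass(frozen=True)
class ItemScenario:
    """Trend definition for one commodity: level and yearly slope per direction."""

    name: str
    sector: str
    unit: str = "t"
    trends: Mapping[str, Tuple[float, float]] = field(default_factory=dict)


def default_items() -> List[ItemScenario]:
    """A small national economy: fertilizer, crops, feed, dairy, fish, oil."""
    return [
        ItemScenario("Fertilizer N", "fertilizer", "t", {
            "production": (288_000, 6_000), "import": (20_000, 0),
            "export": (230_000, 4_800), "domestic_supply": (50_000, 1_000)}),
        ItemScenario("Wheat", "food", "t", {
            "production": (200_000, 1_000), "import": (50_000, 0),
            "export": (10_000, 0)}),
        ItemScenario("Hay", "feed", "t", {"production": (500_000, 2_000)}),
        ItemScenario("Soya bean cake", "feed", "t", {"import": (150_000, 1_000)}),
        ItemScenario("Milk", "dairy", "t", {"production": (1_500_000, 5_000)}),
        ItemScenario("Salmon", "fisheries", "t", {
            "production": (50_000, 1_500), "export": (30_000, 900)}),
        ItemScenario("Petroleum", "fossil", "1000 t", {
            "production": (100_000, 500), "export": (70_000, 350)}),
    ]


@dataclass
class ScenarioSpec:
    """Reproducible description of a synthetic scenario.

    Defaults mirror the conditions of the historical series the budget is
    built from: the 1961-2020 horizon, roughly one interior gap per ten
    years of a series, and a few missing trailing years (statistical
    releases lag 1-6 years).
    """

    seed: int = 0
    years: Tuple[int, int] = DEFAULT_HORIZON
    items: List[ItemScenario] = field(default_factory=default_items)
    gap_fraction: float = 0.10
    tail_missing_years: int = 3
    trend: str = "linear"            # "linear" | "curved"
    noise_sd: float = 0.0            # relative sd of additive noise
    natural_inputs_gg: Mapping[str, float] = field(default_factory=lambda: {
        "non-managed land": 50.0, "forest": 40.0, "agricultural land": 30.0})
    imbalance_injection_gg: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.gap_fraction < 1.0:
            raise ValueError("gap_fraction must lie in [0, 1)")
        if not 0 <= self.tail_missing_years <= 6:
            raise ValueError("tail_missing_years must lie in 0..6")
        if self.trend not in ("linear", "curved"):
            raise ValueError(f"unknown trend {self.trend!r}")


def _trend_value(level: float, slope: float, t: int, span: int, trend: str) -> float:
    value = level + slope * t
    if trend == "curved":
        value += 0.15 * level * (t / max(span, 1)) ** 2
    return max(value, 0.0)


def _truth_quantities(spec: ScenarioSpec) -> pd.DataFrame:
    """Ungapped, noise-free quantities for every item/direction/year."""
    y0, y1 = spec.years
    span = y1 - y0
    rows = []
    for item in spec.items:
        for direction, (level, slope) in sorted(item.trends.items()):
            for year in range(y0, y1 + 1):
                rows.append({
                    "sector": item.sector, "item": item.name, "element": direction,
                    "year": year, "unit": item.unit,
                    "value": _trend_value(level, slope, year - y0, span, spec.trend),
                })
    return pd.DataFrame(rows)


def _item_n_gg(registry: Mapping[str, NItem], name: str, value: float,
               unit: str, direction: str) -> float:
    base = sectors._quantity_to_base(value, unit, registry[name])
    return ncontent.item_nitrogen(registry[name], base, flow=direction) / 1e9


def generate_commodity_table(spec: ScenarioSpec,
                             registry: Optional[Mapping[str, NItem]] = None,
                             ) -> Tuple[Dict[str, pd.DataFrame], pd.DataFrame]:
    """Generate FAO-dialect sector tables and the ground-truth N table.

    Returns ``(tables, truth)``: *tables* maps sector name to a long
    DataFrame with columns Area/Item/Element/Year/Unit/Value, with interior
    gaps and trailing years deleted per the spec; *truth* holds the
    ungapped quantities and their N content (column ``n_gg``) per
    item/element/year, computed with the registry coefficients.
    """
    registry = registry if registry is not None else ncontent.load_registry()
    rng = np.random.default_rng(spec.seed)
    truth = _truth_quantities(spec)
    truth["n_gg"] = [
        _item_n_gg(registry, r.item, r.value, r.unit, r.element)
        for r in truth.itertuples(index=False)
    ]

    y0, y1 = spec.years
    tables: Dict[str, pd.DataFrame] = {}
    for sector, group in truth.groupby("sector", sort=True):
        rows = []
        for (item, element), g in group.groupby(["item", "element"], sort=True):
            g = g.sort_values("year")
            years = g["year"].to_numpy()
            values = g["value"].to_numpy(dtype=float)
            if spec.noise_sd > 0:
                values = np.clip(
                    values * (1 + rng.normal(0.0, spec.noise_sd, len(values))), 0.0, None)
            keep = np.ones(len(years), dtype=bool)
            if spec.tail_missing_years:
                keep[len(years) - spec.tail_missing_years:] = False
            interior = (years > y0) & (years < y1 - spec.tail_missing_years)
            gaps = rng.random(len(years)) < spec.gap_fraction
            keep &= ~(interior & gaps)
            unit = g["unit"].iloc[0]
            for year, value, k in zip(years, values, keep):
                if k:
                    rows.append({"Area": "Synthavia", "Item": item,
                                 "Element": FAO_ELEMENTS[element], "Year": int(year),
                                 "Unit": unit, "Value": float(value)})
        tables[sector] = pd.DataFrame(rows)
    return tables, truth


def generate_raster_fixture(class_fractions: Mapping[str, float],
                            width: int, height: int, seed: int = 0,
                            cell_area_km2: float = 1.0) -> RasterGrid:
    """A shuffled categorical grid whose class counts match the fractions.

    Counts are apportioned by the largest-remainder rule on the normalized
    fractions, so realized counts match requests to the nearest cell; the
    seed only permutes the layout, never the counts.
    """
    n = width * height
    if n <= 0:
        raise ValueError("raster must have at least one cell")
    total = sum(class_fractions.values())
    if any(f < 0 for f in class_fractions.values()):
        raise ValueError("fractions must be non-negative")
    if abs(total - 1.0) > 1.0 / n + 1e-9:
        raise ValueError(f"fractions sum to {total}, off by more than one cell's worth")
    names = sorted(class_fractions)
    quotas = np.array([class_fractions[name] / total * n for name in names])
    counts = np.floor(quotas).astype(int)
    remainder = quotas - counts
    for idx in np.argsort(-remainder)[: n - counts.sum()]:
        counts[idx] += 1
    codes = np.repeat(np.arange(1, len(names) + 1), counts)
    rng = np.random.default_rng(seed)
    rng.shuffle(codes)
    legend = {i + 1: name for i, name in enumerate(names)}
    return RasterGrid(cells=codes.reshape(height, width), legend=legend,
                      cell_area_km2=cell_area_km2)


# -- scenario network -------------------------------------------------


def _n_at_year(truth: pd.DataFrame, year: int) -> Dict[Tuple[str, str], float]:
    at = truth[truth["year"] == year]
    return {(r.item, r.element): r.n_gg for r in at.itertuples(index=False)}


def build_scenario_network(n_gg: Mapping[Tuple[str, str], float],
                           year: int,
                           natural_inputs_gg: Mapping[str, float],
                           imbalance_injection_gg: float = 0.0) -> FlowNetwork:
    """Compose per-item N values into the scenario's closed flow network.

    Pools are balanced by construction: the closing flow of each internal
    pool (leaching, sewage, ocean outflow, denitrification, manure) is
    computed as that pool's residual.  ``imbalance_injection_gg`` is
    withheld from the manure flow, leaving exactly that residual on the
    livestock pool so balance detection can be exercised.
    """

    def n(item: str, element: str) -> float:
        return n_gg.get((item, element), 0.0)

    net = FlowNetwork(year=year)
    add = net.add_flow

    for pool, gg in sorted(natural_inputs_gg.items()):
        add("atmosphere", pool, gg, f"natural inputs to {pool}", year)

    # fertilizer industry
    add("atmosphere", "industry", n("Fertilizer N", "production"), "fertilizer production", year)
    add("rest-of-world", "industry", n("Fertilizer N", "import"), "fertilizer import", year)
    add("industry", "rest-of-world", n("Fertilizer N", "export"), "fertilizer export", year)
    add("industry", "agricultural land", n("Fertilizer N", "domestic_supply"),
        "fertilizer use", year)

    # petroleum
    petro_dom = n("Petroleum", "production") - n("Petroleum", "export")
    if petro_dom < 0:
        raise ValueError("petroleum exports exceed production in scenario")
    add("rest-of-world", "industry", n("Petroleum", "production"), "petroleum production", year)
    add("industry", "rest-of-world", n("Petroleum", "export"), "petroleum export", year)
    add("industry", "people & settlements", petro_dom, "petroleum domestic use", year)
    add("people & settlements", "atmosphere", petro_dom, "fossil combustion NOx", year)
    # industry closure: stock change of fertilizer not used/exported
    ind_res = (n("Fertilizer N", "production") + n("Fertilizer N", "import")
               - n("Fertilizer N", "export") - n("Fertilizer N", "domestic_supply"))
    if ind_res < 0:
        raise ValueError("fertilizer use+export exceed production+import in scenario")
    add("industry", "rest-of-world", ind_res, "fertilizer stock export", year)

    # crops and feed
    add("agricultural land", "people & settlements", n("Wheat", "production"),
        "wheat production", year)
    add("rest-of-world", "people & settlements", n("Wheat", "import"), "wheat import", year)
    add("people & settlements", "rest-of-world", n("Wheat", "export"), "wheat export", year)
    add("agricultural land", "livestock", n("Hay", "production"), "forage feed", year)
    add("rest-of-world", "livestock", n("Soya bean cake", "import"), "imported feed", year)

    # livestock
    feed_in = n("Hay", "production") + n("Soya bean cake", "import")
    manure = feed_in - n("Milk", "production") - imbalance_injection_gg
    if manure < 0:
        raise ValueError("livestock products exceed feed in scenario")
    add("livestock", "people & settlements", n("Milk", "production"), "animal products", year)
    add("livestock", "agricultural land", manure, "manure to soils", year)

    # fisheries
    fish_prod = n("Salmon", "production")
    fish_export = n("Salmon", "export")
    if fish_export > fish_prod:
        raise ValueError("fish exports exceed production in scenario")
    feed = fish_prod / AQUACULTURE_RETENTION
    add("rest-of-world", "fisheries & coastal waters", feed, "aquaculture feed import", year)
    add("fisheries & coastal waters", "hydrosphere", feed - fish_prod,
        "aquaculture feed loss", year)
    add("fisheries & coastal waters", "rest-of-world", fish_export, "fish export", year)
    add("fisheries & coastal waters", "people & settlements", fish_prod - fish_export,
        "fish domestic supply", year)

    # closures: agricultural land -> leaching; people -> sewage;
    # forest -> denitrification; non-managed -> runoff; hydrosphere -> ocean
    agri_in = (natural_inputs_gg.get("agricultural land", 0.0)
               + n("Fertilizer N", "domestic_supply") + manure)
    agri_out = n("Wheat", "production") + n("Hay", "production")
    leaching = agri_in - agri_out
    if leaching < 0:
        raise ValueError("crop N removal exceeds agricultural inputs in scenario")
    add("agricultural land", "hydrosphere", leaching, "leaching", year)

    people_in = (n("Wheat", "production") + n("Wheat", "import") - n("Wheat", "export")
                 + n("Milk", "production") + (fish_prod - fish_export) + petro_dom)
    sewage = people_in - petro_dom  # combustion already routed to atmosphere
    add("people & settlements", "hydrosphere", sewage, "sewage discharge", year)

    add("forest", "atmosphere", natural_inputs_gg.get("forest", 0.0),
        "denitrification", year)
    add("non-managed land", "hydrosphere", natural_inputs_gg.get("non-managed land", 0.0),
        "runoff from non-managed land", year)

    hydro_in = (leaching + sewage + (feed - fish_prod)
                + natural_inputs_gg.get("non-managed land", 0.0))
    add("hydrosphere", "rest-of-world", hydro_in, "river and coastal outflow", year)
    return net


def generate_full_scenario(spec: ScenarioSpec) -> dict:
    """All inputs the pipeline needs, plus the expected balanced network.

    Returns a bundle dict with the registry, the sector ``tables``, the
    ground-truth ``truth`` table, a biome ``raster`` and the
    ``expected_network`` for the last horizon year, whose only internal
    residual is the injected imbalance (on the livestock pool).
    """
    registry = ncontent.load_registry()
    tables, truth = generate_commodity_table(spec, registry)
    raster = generate_raster_fixture(
        {"tundra": 0.617, "boreal": 0.317, "temperate": 0.066},
        width=40, height=25, seed=spec.seed)
    budget_year = spec.years[1]
    expected = build_scenario_network(
        _n_at_year(truth, budget_year), budget_year,
        spec.natural_inputs_gg, spec.imbalance_injection_gg)
    return {"spec": spec, "registry": registry, "tables": tables, "truth": truth,
            "raster": raster, "budget_year": budget_year, "expected_network": expected}


def run_pipeline(bundle: dict) -> FlowNetwork:
    """Recompute the scenario network through the full accounting pipeline.

    Tables are parsed into annual series, repaired (interior interpolation
    plus tail extension), converted to N through the registry, and composed
    with the same network builder the ground truth used — so any
    discrepancy against ``expected_network`` localizes to parsing, repair
    or conversion.
    """
    from .io import series_from_frame  # local import to avoid a cycle

    spec: ScenarioSpec = bundle["spec"]
    registry = bundle["registry"]
    year = bundle["budget_year"]
    n_gg: Dict[Tuple[str, str], float] = {}
    for sector, frame in bundle["tables"].items():
        series = [fill_series(s) for s in series_from_frame(frame)]
        accounts = sectors.commodity_sector_account(series, registry, sector)
        if year in accounts:
            for flow in accounts[year].flows:
                item, _, element = flow.label.rpartition(" (")
                n_gg[(item, element.rstrip(")"))] = flow.n_grams / 1e9
    return build_scenario_network(n_gg, year, spec.natural_inputs_gg,
                                  spec.imbalance_injection_gg)
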