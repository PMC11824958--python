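"""Biome areas and biome-rate estimates of natural nitrogen inputs.

Natural N enters the landscape through atmospheric deposition, biological
N fixation (BNF) and rock weathering, at rates (kg N ha-1 yr-1) that are
characteristic of the biome.  Multiplying biome-specific rates by the area
each biome covers and summing yields a national total.  Areas are obtained
by counting cells of a categorical raster (a biome or climate-zone map
masked to the country outline, already in an equal-area projection), or by
mapping Koppen-Geiger climate-zone fractions onto biomes.

Denitrification — the microbial return of nitrate to N2 — is estimated by
applying a per-hectare rate to the soil-covered (non-unproductive) land.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Mapping, Optional

import numpy as np

#: Mainland Norway (Fastlands-Norge) land area, km2.
COUNTRY_AREA_KM2 = 323_808.0

#: Biome areas (km2) from the WWF terrestrial-ecoregion map of the country.
WWF_BIOME_AREAS_KM2: Dict[str, float] = {
    "tundra": 199_687.0,
    "boreal": 102_585.0,
    "temperate": 21_536.0,
}

#: Koppen-Geiger climate code -> WWF biome.
KOPPEN_TO_BIOME: Dict[str, str] = {
    "Cfb": "temperate",
    "Cfc": "temperate",
    "Dfb": "temperate",
    "Dsc": "boreal",
    "Dsb": "boreal",
    "Dfc": "boreal",
    "ET": "tundra",
    "EF": "polar desert",
}

# Country cover fractions (%) by Koppen-Geiger zone.  The climate-map
# quantification lumps the small Dsc area with ET and counts the lump as
# tundra, so it is carried here under its dominant code ET.
KOPPEN_FRACTIONS_PRESENT = {"Cfb": 11.41, "Dfc": 56.23, "ET": 28.09, "EF": 4.27}
KOPPEN_FRACTIONS_FUTURE = {"Cfb": 57.35, "Dfc": 41.38, "ET": 1.27, "EF": 0.0}

# Biome-specific rates, kg N ha-1 yr-1, by flux and epoch.  "current" rates
# come from recent deposition/BNF syntheses; "preindustrial"/"industrial"
# from reconstructions.  The polar desert receives zero for every flux (no
# published rates), and rock weathering has no "current" estimate.
BIOME_RATES: Dict[str, Dict[str, Dict[str, float]]] = {
    "deposition": {
        "preindustrial": {"tundra": 0.08, "boreal": 0.35, "temperate": 1.88, "polar desert": 0.0},
        "industrial": {"tundra": 0.31, "boreal": 1.47, "temperate": 5.7, "polar desert": 0.0},
        "current": {"tundra": 1.14, "boreal": 2.84, "temperate": 10.57, "polar desert": 0.0},
    },
    "fixation": {
        "preindustrial": {"tundra": 0.46, "boreal": 0.71, "polar desert": 0.0},
        "industrial": {"tundra": 1.12, "boreal": 2.12, "polar desert": 0.0},
        "current": {"tundra": 3.2, "boreal": 2.1, "polar desert": 0.0},
        "recent": {"tundra": 6.1, "boreal": 1.8, "polar desert": 0.0},
    },
    "weathering": {
        "preindustrial": {"tundra": 0.54, "boreal": 0.77, "polar desert": 0.0},
        "industrial": {"tundra": 1.04, "boreal": 1.47, "polar desert": 0.0},
    },
}

#: Natural-input totals used for the 2018 budget (Gg N yr-1).  These are the
#: budget's configured values; the flux estimators above recompute the
#: traceable ones (deposition) from rates x areas.
NATURAL_INPUTS_2018_GG = {"deposition": 50.7, "fixation": 79.9, "weathering": 47.6}

#: How the natural-input total is partitioned onto land pools (Gg N yr-1).
LAND_ALLOCATION_2018_GG = {
    "non-managed land": 92.8,
    "forest": 61.2,
    "agricultural land": 22.2,
}

#: Denitrification: rate observed for Western European coniferous forest
#: soils, applied to the non-unproductive land area.
DENITRIFICATION_RATE_KG_HA_YR = 0.57
UNPRODUCTIVE_LAND_FRACTION = 0.086
TOTAL_LAND_AREA_HA = 38_520_700.0


@dataclass
class RasterGrid:
    """A categorical class grid with a country mask and per-cell area."""

    cells: np.ndarray                 # int class codes, shape (H, W)
    legend: Dict[int, str]            # code -> class name
    cell_area_km2: float = 1.0
    mask: Optional[np.ndarray] = None  # bool, True = inside country

    def __post_init__(self):
        self.cells = np.asarray(self.cells)
        if self.cells.ndim != 2:
            raise ValueError("cells must be a 2-D grid")
        if self.mask is None:
            self.mask = np.ones(self.cells.shape, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.cells.shape:
            raise ValueError("mask shape must match cells shape")
        codes = np.unique(self.cells[self.mask])
        unknown = [int(c) for c in codes if int(c) not in self.legend]
        if unknown:
            raise ValueError(f"masked cells contain codes missing from legend: {unknown}")

    @property
    def masked_area_km2(self) -> float:
        return float(self.mask.sum()) * self.cell_area_km2

    @classmethod
    def from_text(cls, path: str | Path, legend: Dict[int, str],
                  cell_area_km2: float = 1.0, mask_code: Optional[int] = None) -> "RasterGrid":
        """Read a whitespace-separated integer grid; *mask_code* cells are outside."""
        cells = np.loadtxt(path, dtype=int)
        mask = None if mask_code is None else cells != mask_code
        legend = {c: n for c, n in legend.items() if mask_code is None or c != mask_code}
        return cls(cells=cells, legend=legend, cell_area_km2=cell_area_km2, mask=mask)


def quantify_raster_areas(grid: RasterGrid) -> Dict[str, Dict[str, float]]:
    """Per-class masked cell counts, areas and fractions.

    Fractions are relative to the masked (inside-country) cell count and
    sum to 1.
    """
    n_masked = int(grid.mask.sum())
    if n_masked == 0:
        raise ValueError("empty mask: no cells inside the country outline")
    codes, counts = np.unique(grid.cells[grid.mask], return_counts=True)
    out: Dict[str, Dict[str, float]] = {}
    for code, count in zip(codes, counts):
        name = grid.legend[int(code)]
        out[name] = {
            "cells": int(count),
            "area_km2": float(count) * grid.cell_area_km2,
            "fraction": float(count) / n_masked,
        }
    return out


def map_koppen_to_biomes(zone_fractions: Mapping[str, float],
                         mapping: Mapping[str, str] = KOPPEN_TO_BIOME) -> Dict[str, float]:
    """Aggregate Koppen-zone fractions into biome fractions.

    Compound keys like ``"Dsc/ET"`` are allowed when all member codes map
    to the same biome.
    """
    out: Dict[str, float] = {}
    for zone, frac in zone_fractions.items():
        if frac < 0:
            raise ValueError(f"negative fraction for zone {zone!r}")
        codes = [c.strip() for c in zone.replace(",", "/").split("/") if c.strip()]
        biomes = set()
        for code in codes:
            if code not in mapping:
                raise KeyError(f"Koppen code {code!r} has no biome mapping")
            biomes.add(mapping[code])
        if len(biomes) != 1:
            raise ValueError(f"zone key {zone!r} spans several biomes {sorted(biomes)}")
        biome = biomes.pop()
        out[biome] = out.get(biome, 0.0) + float(frac)
    return out


def get_rate(flux: str, epoch: str, biome: str) -> float:
    try:
        by_epoch = BIOME_RATES[flux]
    except KeyError:
        raise KeyError(f"unknown flux {flux!r}; expected one of {sorted(BIOME_RATES)}")
    try:
        by_biome = by_epoch[epoch]
    except KeyError:
        raise KeyError(f"flux {flux!r} has no epoch {epoch!r} (have {sorted(by_epoch)})")
    try:
        return by_biome[biome]
    except KeyError:
        raise KeyError(f"no {flux!r}/{epoch!r} rate for biome {biome!r}")


def biome_flux_total(areas_km2: Mapping[str, float], flux: str, epoch: str,
                     rates: Optional[Mapping[str, Mapping[str, Mapping[str, float]]]] = None) -> float:
    """Total national flux (Gg N yr-1) = sum over biomes of area x rate.

    Areas are km2 (x100 -> ha), rates kg N ha-1 yr-1; 1 Gg = 1e6 kg.
    """
    total_kg = 0.0
    for biome, area in areas_km2.items():
        if area < 0:
            raise ValueError(f"negative area for biome {biome!r}")
        if area == 0:
            continue
        if rates is not None:
            rate = rates[flux][epoch][biome]
        else:
            rate = get_rate(flux, epoch, biome)
        total_kg += area * 100.0 * rate
    return total_kg / 1e6


def denitrification_loss(total_area_ha: float = TOTAL_LAND_AREA_HA,
                         unproductive_fraction: float = UNPRODUCTIVE_LAND_FRACTION,
                         rate_kg_n_ha_yr: float = DENITRIFICATION_RATE_KG_HA_YR) -> float:
    """Denitrification loss (Gg N yr-1) over the soil-covered land area."""
    if not 0.0 <= unproductive_fraction <= 1.0:
        raise ValueError("unproductive_fraction must lie in [0, 1]")
    if rate_kg_n_ha_yr < 0 or total_area_ha < 0:
        raise ValueError("area and rate must be non-negative")
    return total_area_ha * (1.0 - unproductive_fraction) * rate_kg_n_ha_yr / 1e6
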