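"""Readers and writers for the table dialects, plus run configuration.

The canonical input dialect is the FAO long format: comma-separated UTF-8
with a header row and columns Area / Item / Element / Year / Unit / Value
(decimal point, no thousands separators).  One annual series is built per
(Item, Element) pair; a blank Value cell makes that year missing (absence
of a row means the same), while an explicit 0 is an observation.

All writers are atomic: content goes to a temp file that is renamed over
the target, so re-running a command on unchanged inputs yields
byte-identical outputs and a crash never leaves a half-written file.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Tuple

import pandas as pd
import yaml

from .series import DEFAULT_HORIZON, AnnualSeries

log = logging.getLogger("nbudget")

REQUIRED_COLUMNS = ("Item", "Element", "Year", "Unit", "Value")

#: FAO element label (lowercased) -> internal direction.
ELEMENT_ALIASES: Dict[str, str] = {
    "production": "production",
    "import quantity": "import",
    "import": "import",
    "export quantity": "export",
    "export": "export",
    "domestic supply quantity": "domestic_supply",
    "domestic supply": "domestic_supply",
    "agricultural use": "domestic_supply",
}


def normalize_element(element: str) -> str:
    return ELEMENT_ALIASES.get(element.strip().lower(), "other")


def series_from_frame(frame: pd.DataFrame,
                      horizon: Tuple[int, int] = DEFAULT_HORIZON) -> List[AnnualSeries]:
    """Build one AnnualSeries per (Item, Element) from a long table."""
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"missing required column(s): {missing}")
    out: List[AnnualSeries] = []
    for (item, element), group in frame.groupby(["Item", "Element"], sort=True):
        units = sorted(set(group["Unit"].astype(str)))
        if len(units) > 1:
            raise ValueError(f"{item}/{element}: mixed units {units}")
        values: Dict[int, float] = {}
        for row in group.itertuples():
            raw = row.Value
            if raw is None or (isinstance(raw, str) and not raw.strip()) or pd.isna(raw):
                log.warning("%s/%s year %s: blank value treated as missing",
                            item, element, row.Year)
                continue
            try:
                year = int(row.Year)
                value = float(raw)
            except (TypeError, ValueError):
                raise ValueError(
                    f"{item}/{element} row {row.Index}: non-numeric "
                    f"Year/Value ({row.Year!r}, {raw!r})")
            values[year] = value
        out.append(AnnualSeries(item=str(item), element=normalize_element(str(element)),
                                unit=units[0], values=values, horizon=horizon))
    return out


def read_long_table(path: str | Path,
                    expected_columns: Tuple[str, ...] = REQUIRED_COLUMNS,
                    horizon: Tuple[int, int] = DEFAULT_HORIZON) -> List[AnnualSeries]:
    """Read a long-format CSV into annual series (one per item/element)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path)
    missing = [c for c in expected_columns if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {missing}")
    return series_from_frame(frame, horizon=horizon)


def atomic_write_text(path: str | Path, payload: str) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tmp = path.with_name(path.name + ".tmp")
    tmp.write_text(payload, encoding="utf-8")
    os.replace(tmp, path)
    return path


def write_frame(frame: pd.DataFrame, path: str | Path) -> Path:
    return atomic_write_text(path, frame.to_csv(index=False))


@dataclass
class Config:
    """Run configuration for a budget computation.

    Paths point at the coefficient registry, sector tables and raster;
    the constants block carries the documented overrides (country area,
    natural-input totals, NOx/NH3 conversion mode, interpolation caps).
    """

    registry_path: Optional[str] = None
    sector_tables: Dict[str, str] = field(default_factory=dict)
    raster_path: Optional[str] = None
    output_dir: str = "out"
    country_area_km2: float = 323_808.0
    natural_inputs_gg: Dict[str, float] = field(default_factory=dict)
    emission_mode: str = "reporting"
    max_tail_years: int = 6
    log_level: str = "INFO"

    def __post_init__(self):
        if self.emission_mode not in ("reporting", "stoichiometric"):
            raise ValueError(f"unknown emission mode {self.emission_mode!r}")
        if not 0 <= self.max_tail_years <= 6:
            raise ValueError("max_tail_years must lie in 0..6")
        if self.country_area_km2 <= 0:
            raise ValueError("country area must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Config":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        cfg = cls(**data)
        for name, p in [("registry", cfg.registry_path), ("raster", cfg.raster_path),
                        *[(f"table {s}", p) for s, p in cfg.sector_tables.items()]]:
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"configured {name} path does not exist: {p}")
        for key, value in sorted(vars(cfg).items()):
            log.info("config %s = %r", key, value)
        return cfg
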