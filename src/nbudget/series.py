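"""Annual commodity series with the budget's gap-filling rules.

Statistical series for traded and produced commodities frequently have
interior gaps and a few missing trailing years.  Two repairs are applied
before any N accounting:

* interior gaps between two observed years are filled by linear
  interpolation of the flanking observations;
* up to six trailing years after the last observation are carried forward
  from the last observed value (a flat extension).

Leading gaps (years before the first observation) are never filled.  Every
year carries a provenance status so downstream code can distinguish
observed from repaired data.  An explicit value of 0 in an input table is
an observation; absence of a row is a missing year.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, Tuple

OBSERVED = "observed"
INTERPOLATED = "interpolated"
EXTENDED = "extended"
MISSING = "missing"

#: Default budget horizon, inclusive.
DEFAULT_HORIZON: Tuple[int, int] = (1961, 2020)

#: Conversion used for oil rates reported as "1 barrel per day".
TONNES_PER_YEAR_PER_BARREL_PER_DAY = 48.80


@dataclass(frozen=True)
class AnnualSeries:
    """Yearly values for one (item, element) pair with per-year provenance.

    ``values`` maps year -> value for years that have one; years absent
    from ``values`` are missing.  ``status`` is maintained in lockstep.
    """

    item: str
    element: str = "other"
    unit: str = "t"
    values: Dict[int, float] = field(default_factory=dict)
    status: Dict[int, str] = field(default_factory=dict)
    horizon: Tuple[int, int] = DEFAULT_HORIZON

    def __post_init__(self):
        # Default any un-annotated value to an observation.
        status = dict(self.status)
        for year in self.values:
            status.setdefault(year, OBSERVED)
        extra = set(status) - set(self.values)
        if extra:
            raise ValueError(f"status given for valueless years {sorted(extra)}")
        object.__setattr__(self, "status", status)

    @classmethod
    def from_observations(
        cls,
        item: str,
        values: Dict[int, float],
        element: str = "other",
        unit: str = "t",
        horizon: Tuple[int, int] = DEFAULT_HORIZON,
    ) -> "AnnualSeries":
        return cls(item=item, element=element, unit=unit,
                   values=dict(values), status={y: OBSERVED for y in values},
                   horizon=horizon)

    @property
    def observed_years(self) -> list[int]:
        return sorted(y for y, s in self.status.items() if s == OBSERVED)

    def year_status(self, year: int) -> str:
        return self.status.get(year, MISSING)

    def __getitem__(self, year: int) -> float:
        return self.values[year]

    def years(self) -> Iterable[int]:
        return range(self.horizon[0], self.horizon[1] + 1)


def interpolate_gaps(series: AnnualSeries) -> AnnualSeries:
    """Fill interior missing years by linear interpolation.

    Every missing year strictly between two observed years receives the
    value of the straight line through the nearest flanking observations
    and is flagged ``interpolated``.  Years outside the observed span are
    untouched.  Idempotent: interpolated years are not observations and
    are recomputed identically on a second pass.
    """
    obs = series.observed_years
    if not obs:
        raise ValueError(f"no observations in series {series.item!r}/{series.element}")
    values = dict(series.values)
    status = dict(series.status)
    for y0, y1 in zip(obs, obs[1:]):
        if y1 - y0 <= 1:
            continue
        v0, v1 = series.values[y0], series.values[y1]
        for year in range(y0 + 1, y1):
            if status.get(year) == OBSERVED:
                continue
            values[year] = v0 + (v1 - v0) * (year - y0) / (y1 - y0)
            status[year] = INTERPOLATED
    return replace(series, values=values, status=status)


def extend_tail(series: AnnualSeries, max_years: int = 6) -> AnnualSeries:
    """Carry the last observed value forward over trailing missing years.

    At most *max_years* years after the last observation are filled (flat)
    and flagged ``extended``; anything beyond stays missing.  The horizon
    end bounds the extension.
    """
    if max_years < 0:
        raise ValueError("max_years must be >= 0")
    obs = series.observed_years
    if not obs:
        raise ValueError(f"no observations in series {series.item!r}/{series.element}")
    last = obs[-1]
    values = dict(series.values)
    status = dict(series.status)
    stop = min(last + max_years, series.horizon[1])
    for year in range(last + 1, stop + 1):
        if status.get(year) == OBSERVED:
            break
        values[year] = series.values[last]
        status[year] = EXTENDED
    return replace(series, values=values, status=status)


def fill_series(series: AnnualSeries, max_tail_years: int = 6) -> AnnualSeries:
    """Standard repair pipeline: interior interpolation then tail extension."""
    return extend_tail(interpolate_gaps(series), max_tail_years)


def barrels_per_day_to_tonnes_per_year(rate: float) -> float:
    """Convert an oil flow of *rate* barrels per day to tonnes per year."""
    if rate < 0:
        raise ValueError("rate must be non-negative")
    return rate * TONNES_PER_YEAR_PER_BARREL_PER_DAY
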