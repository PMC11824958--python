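# Methods

## Scope and model

The package performs substance-flow accounting for nitrogen at national
scale. The bookkeeping unit is grams of N (displayed as Mg/Gg); every
computation is a linear map from reported commodity quantities, population
counts or land areas to N mass, followed by composition into a directed
flow network over ten pools. Two pools are boundaries (atmosphere,
rest-of-world); the other eight are internal and expected to balance only
on closed synthetic scenarios. For real statistics, residuals are reported,
never corrected: an unbalanced pool (for instance livestock, where reported
feed N exceeds reported product N plus collected manure N by tens of Gg) is
a finding about the data, and silently forcing closure would destroy it.

Residual arithmetic uses `fractions.Fraction` over the flow list.
`Fraction(float)` is exact, so the identity "sum of all residuals is zero"
holds with no tolerance; tolerances appear only where two independently
computed float quantities are compared.

## Series repair

Commodity statistics carry interior gaps and lag by a few years. Repair is:

1. interior missing years strictly between two observations get the linear
   interpolation of the flanking observed values;
2. up to six trailing missing years are carried forward flat from the last
   observation;
3. leading gaps are never filled — there is no anchor on the left, and
   extrapolating backwards would invent history.

Every repaired year is flagged (`interpolated` / `extended`), observed
values are never overwritten, and repair is idempotent. An explicit 0 in a
table is an observation; a missing row is a missing year. Both rules are
needed for interpolation to be well defined.

## Conversion coefficients

All converters are linear and vanish at zero; the tests assert additivity
and scale invariance across the whole registry. Parameters that matter:

| parameter | value | unit | role |
|---|---|---|---|
| Jones' factor | 6.25 | g protein / g N | protein → N |
| non-protein N uplift | 1.15 | – | nucleic acids etc. in food items |
| dressed-weight factor | 0.7 | – | carcass / live weight |
| protein per meat | 0.18 | – | live-animal chain |
| N per protein | 0.16 | – | 1/Jones |
| wood density | 400 / 500 | kg m⁻³ | conifer / non-conifer basic density |
| wood N fraction | 0.14 / 0.17 / 0 | % dry wt | conifer / non-conifer / pulp |
| petroleum N | 0.4 | % wt | continental-shelf crude average |
| bituminous coal N | 2.0 | % wt | coke: 2 % in production, 0 in trade |
| NOx N fraction | 0.44 (reporting) / 0.4585 (stoichiometric) | – | 95 % NO, 5 % NO₂ |
| NH₃ N fraction | 0.82 (reporting) / 14/17 | – | |
| fish usable fraction | 0.75 | – | of caught fresh weight, then per-item N |
| barrel conversion | 48.80 | t yr⁻¹ per bbl day⁻¹ | oil rate unit change |

The NOx reporting constant and the stoichiometric mixture disagree (0.44
vs 0.4585); the reporting constant is the default because it is what the
emission statistics embed, and the stoichiometric mode exists for
sensitivity analysis. Similarly the per-person breath/skin pathway uses
0.833 as its N/NH₃ factor (its source convention) while 14/17 = 0.8235 is
the chemical value; both are kept as named constants rather than silently
unified.

The per-item coefficient registry (`data/coefficients.csv`) is a synthetic
registry: its protein/N fractions are standard food-composition magnitudes,
sufficient to exercise every conversion rule, and are not calibrated
against any published per-item table. Unknown items fail loudly; nothing
defaults.

## Biome-based natural inputs

Deposition, biological fixation and weathering are estimated as
area-weighted biome rates (kg N ha⁻¹ yr⁻¹ over tundra / boreal / temperate
areas; the polar desert gets zero for lack of published rates, and
weathering has no current-epoch rate). Areas come from counting cells of a
categorical raster masked to the country outline; the raster is consumed
already in an equal-area projection with a stated cell area, so
reprojection is out of scope. Climate-zone fractions can be folded onto
biomes through the Köppen mapping; a compound zone key is accepted only
when all member codes map to one biome — the national zone data lumps the
small Dsc area with ET under tundra, so that lump is carried under ET.

The deposition estimator reproduces its reference totals (74.7 current /
33.5 industrial Gg N yr⁻¹) from rates × areas. Fixation and weathering
totals for 2018 (79.9 and 47.6 Gg, with deposition 50.7) are not derivable
from the printed rate tables and are therefore configuration constants of
the 2018 budget, kept separate from the estimators. The land-pool
partition of the natural input (92.8 / 61.2 / 22.2 Gg) is likewise
configuration; note its sum (176.2) differs from the input total (178.2)
by 2.0 Gg, which the balance report surfaces rather than hides.

In the network topology, natural-input allocation flows enter land pools
from the atmosphere. Deposition and fixation genuinely are atmospheric;
rock weathering rides along because the pool taxonomy has no lithosphere
pool, and splitting a 47.6 Gg input across an extra pool would buy no
analytical power.

## The 2018 reference flow table

`data/flows_2018.csv` transcribes only flows that are individually
reported (≈42 of the 64 resolved flows); each row's `note` column states
what the flow is so the table is auditable. Aggregate trade totals
(import 504.77 / export 1417.84 Gg) are reference constants, not rows —
as rows they would double-count the itemized trade flows, so
`total_trade()` on the shipped table is deliberately below the aggregate.
Fisheries capture (63.4 Gg) and aquaculture production (37.19 Gg) are
internal to the fisheries & coastal-waters pool and are likewise constants.

## Synthetic data

The generator emulates the features of the real inputs that the pipeline
must survive: the FAO long CSV dialect (Area/Item/Element/Year/Unit/Value),
a 1961–2020 horizon, interior gaps (default fraction 0.10) and missing
trailing years (default 3, within the 1–6 range statistical releases lag
by), per-item coefficients spanning every conversion basis, and a labeled
raster with known class counts. Trends are piecewise linear by default so
interpolation-based repair is exact and recovery tests are sharp
(tolerance 1e-9 relative); a quadratic trend and multiplicative noise
exist for robustness tests, where the interpolation error is bounded by
the trend's maximum second difference × (gap width / 2)².

Scenario networks are balanced by construction: each internal pool's
closing flow (leaching, sewage, denitrification, runoff, ocean outflow,
manure) is computed as its residual, and a configurable imbalance can be
withheld from the manure flow to verify that balance detection localizes
it to the livestock pool. Raster class counts are apportioned by the
largest-remainder rule, so the seed permutes layout but never counts.

What passing synthetic tests does **not** show: the generator has no
revision history, no unit heterogeneity within a series, no correlated
reporting errors, and linear trends flatter than real commodity series —
so exact recovery on synthetic data demonstrates the pipeline loses no
information, not that repaired real series equal the unobserved truth.

## Problem sizes and numerical choices

The default test scenarios use 7 items × up to 4 directions × 60 years
(≈1 400 table rows) and 1 000-cell rasters, sizes at which every
closed-form check is exact and the full suite runs in seconds. Ties in
raster apportionment resolve by class-name order (deterministic);
degenerate inputs (zero feed, zero population, empty masks, unknown items,
fractions outside [0, 1]) raise with the offending name rather than
propagating NaN. File writes are atomic (temp file + rename) and
re-running any command on unchanged inputs is byte-identical.

## Known limitations

- The livestock, forest and people pools of the 2018 table are genuinely
  unbalanced; the package reports, and cannot resolve, those gaps.
- Manure leaching/volatilization splits between pasture-left and applied
  manure are allocated pro-rata when only totals are known.
- No uncertainty propagation: every coefficient is a point value.
- Sub-annual dynamics, soil N stocks and atmospheric transport modelling
  are out of scope; the biome-rate estimators are averages over large and
  heterogeneous environments and should be read as order-of-magnitude
  anchors, not measurements.
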