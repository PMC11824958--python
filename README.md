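# nbudget — national nitrogen mass-flow accounting

`nbudget` builds a national nitrogen (N) budget in the substance-flow-analysis
tradition: every commodity a country produces, trades and consumes is
converted to the mass of N it carries, the natural N inputs of the landscape
are estimated from biome-specific rates, and the resulting flows are composed
into a directed pool network (atmosphere, hydrosphere, land pools, livestock,
fisheries, people, industry, rest-of-world) whose balance residuals expose
gaps in data or models. The reference application is mainland Norway
(Fastlands-Norge, 323 808 km²) with its 2018 flow table shipped as a fixture,
but every stage is generic and fully exercised on synthetic data.

It is written for environmental biogeochemists and nutrient-accounting
practitioners who want the bookkeeping to be reproducible, testable and
auditable rather than locked in a spreadsheet.

## The accounting model

All flows are N masses per year (Gg = 10⁹ g). The item-level conversions are
linear rules:

- protein-bearing items: `m_N = m · p · (1/6.25) · 1.15` with `p` the protein
  fraction, 6.25 Jones' factor, and a 15 % uplift for non-protein N;
- live animals: `m_N = m_live · 0.7 · 0.18 · 0.16` (dressed weight, protein
  per meat, N per protein);
- roundwood: `m_N = V · ρ · w` with basic density ρ (400/500 kg m⁻³ for
  conifer/non-conifer) and dry-wood N fraction w (0.14 %/0.17 %); pulp and
  paper carry 0;
- fossil fuels: 0.4 % (petroleum) and 2.0 % (bituminous coal) by weight,
  metallurgical coke 2 % in production but 0 in trade;
- airborne emissions: NOx-N = 0.44·m(NOx) (or the stoichiometric
  0.95·14/30 + 0.05·14/46), NH₃-N = 0.82·m(NH₃) (or 14/17).

Natural inputs are area-weighted biome rates,
`F = Σ_b A_b · r_b` (kg N ha⁻¹ yr⁻¹ over tundra/boreal/temperate areas),
for atmospheric deposition, biological N fixation and rock weathering.
Annual series are repaired before conversion: interior gaps by linear
interpolation between flanking observations, up to six trailing missing
years by carrying the last observation forward; every year keeps a
provenance flag.

Pool residuals (inflow − outflow) are computed with exact rational
arithmetic, so the global identity Σ residuals = 0 holds as a mathematical
fact of the flow list, and any nonzero internal residual is a statement
about the data, not about floating point.

## Worked example

```
$ nbudget check-2018
2018 worked-quantity cross-checks:
  [PASS] denitrification loss                   computed       20.069 vs 20.1 Gg N/yr (tol 0.1)
  [PASS] biome deposition, current rates        computed       74.662 vs 74.7 Gg N/yr (tol 0.1)
  [PASS] biome deposition, industrial rates     computed       33.546 vs 33.5 Gg N/yr (tol 0.1)
  [PASS] natural inputs total                   computed        178.2 vs 178.2 Gg N/yr (tol 0.1)
  [PASS] aquaculture feed N                     computed       124.16 vs 124 Gg N/yr (tol 1)
  [PASS] aquaculture retention                  computed      0.32984 vs 0.33 fraction (tol 0.01)
  [PASS] livestock conversion rate              computed      0.17384 vs 0.174 fraction (tol 0.001)
  ...
16/16 checks passed
```

Each line recomputes one desk-scale quantity of the 2018 budget from its
stated inputs — e.g. denitrification is 38 520 700 ha of land, minus the
8.6 % unproductive share, times 0.57 kg N ha⁻¹ yr⁻¹ ≈ 20.1 Gg N yr⁻¹; the
livestock feed-conversion rate is 28.54 Gg of product N over the
164.17 Gg feed-N aggregate ≈ 0.174 — and compares it at the precision the
reference value is reported with.

Other entry points:

```
nbudget budget --year 2018 --out out/    # flow CSV/JSON/DOT + balance report
nbudget synth --seed 1 --out synth_out/  # synthetic scenario bundle
nbudget sectors --table food food.csv --out out/
nbudget biome --raster grid.txt --legend 1 boreal ... --cell-area 100
```

From Python:

```python
from nbudget.budget import load_reference_flows
net = load_reference_flows(2018)
print(net.pool_balance("livestock"))   # +37.83 Gg: reported feed exceeds
                                       # reported products + collected manure
imports, exports = net.total_trade()
```

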