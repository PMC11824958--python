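"""Sector-level accounts: manure, efficiencies, people, waste, commodities."""

import pytest

from nbudget import sectors
from nbudget.ncontent import NItem
from nbudget.sectors import (
    ManureAccount,
    SectorAccount,
    aquaculture_retention,
    biowaste_nitrogen,
    commodity_sector_account,
    emissions_account,
    livestock_conversion_rate,
    manure_retention,
    migration_nitrogen,
    people_breath_skin_emission,
    per_capita_protein_supply,
    sewage_per_capita,
    sludge_nitrogen,
)
from nbudget.series import AnnualSeries


class TestManure:
    def test_pro_rata_worked_example(self):
        # direct-substitution oracle: retained = (Np+Na) - leached - volatile
        acc = manure_retention(ManureAccount.from_totals(
            2018, n_excreted=100.0, n_pasture=49.0, n_applied=48.0,
            leached_total=29.0, volatile_total=19.5))
        assert acc.n_retained == pytest.approx(48.5)
        assert acc.pct_retained == pytest.approx(48.5)
        assert acc.n_loss == pytest.approx(51.5)

    def test_no_losses_full_retention(self):
        acc = manure_retention(ManureAccount(2000, 10.0, 6.0, 4.0))
        assert acc.pct_retained == pytest.approx(100.0)
        assert acc.n_loss == pytest.approx(0.0)

    def test_retention_trend_direction(self):
        # retention share drifting up over a synthetic decade (41% -> 43%)
        pcts = []
        for i in range(10):
            frac = 0.41 + 0.002 * i
            acc = manure_retention(ManureAccount.from_totals(
                1960 + i, 100.0, 50.0, 50.0,
                leached_total=(1 - frac) * 100.0, volatile_total=0.0))
            pcts.append(acc.pct_retained)
        assert pcts == sorted(pcts)
        assert pcts[0] == pytest.approx(41.0) and pcts[-1] == pytest.approx(42.8)

    def test_zero_excretion_with_components_rejected(self):
        with pytest.raises(ValueError):
            manure_retention(ManureAccount(2000, 0.0, 1.0, 0.0))

    def test_bounded_when_losses_bounded(self):
        acc = manure_retention(ManureAccount(2000, 50.0, 25.0, 25.0,
                                             n_pasture_leached=10.0,
                                             n_applied_volatile=5.0))
        assert 0.0 <= acc.pct_retained <= 100.0


class TestEfficiencies:
    def test_aquaculture_retention_2018(self):
        assert aquaculture_retention(40.9, 124.0) == pytest.approx(0.33, abs=0.01)
        # within two points of the 34 % literature value
        assert abs(aquaculture_retention(40.9, 124.0) - 0.34) < 0.02

    def test_aquaculture_edge_cases(self):
        assert aquaculture_retention(5.0, 5.0) == 1.0
        with pytest.raises(ValueError):
            aquaculture_retention(1.0, 0.0)

    def test_livestock_conversion_2018(self):
        components = [80.25, 4.17, 48.29, 31.46]
        assert sum(components) == pytest.approx(164.17)
        assert livestock_conversion_rate(28.54, components) == pytest.approx(
            0.174, abs=0.001)

    def test_livestock_conversion_identity(self):
        assert livestock_conversion_rate(7.0, 7.0) == 1.0


class TestPeople:
    def test_per_capita_supply_scaling(self):
        assert per_capita_protein_supply(365.0, 1) == pytest.approx(1.0)
        base = per_capita_protein_supply(1e9, 5_000_000)
        assert per_capita_protein_supply(1e9, 10_000_000) == pytest.approx(base / 2)

    def test_per_capita_supply_2010s_magnitude(self):
        # ~160 g/day for 5.3 M people -> ~310 kt protein per year
        total = 160.0 * 365 * 5_300_000
        assert per_capita_protein_supply(total, 5_300_000) == pytest.approx(160.0)

    def test_breath_skin_population_total(self):
        assert people_breath_skin_emission(5_000_000) / 1e6 == pytest.approx(
            29.2, abs=0.1)

    def test_breath_skin_single_person(self):
        # 0.8e-3 g/h * 0.833 * 8760 h
        assert people_breath_skin_emission(1) == pytest.approx(5.838, abs=0.01)
        assert people_breath_skin_emission(0) == 0.0

    def test_migration_sign_symmetry(self):
        n_in = migration_nitrogen(18_103)
        assert n_in / 1e6 == pytest.approx(27.0, abs=0.5)  # ~27 Mg
        assert migration_nitrogen(-18_103) == pytest.approx(-n_in)
        assert migration_nitrogen(0) == 0.0


class TestSewageWaste:
    def test_sludge_totals(self):
        assert sludge_nitrogen(111.7e9) / 1e9 == pytest.approx(2.8, abs=0.05)
        assert sludge_nitrogen(92.1e9) / 1e9 == pytest.approx(2.3, abs=0.05)
        assert sludge_nitrogen(0.0) == 0.0

    def test_sludge_fraction_bounds(self):
        with pytest.raises(ValueError):
            sludge_nitrogen(1.0, n_fraction=1.5)

    @pytest.mark.parametrize("kg_yr,g_day", [(3.51, 9.62), (3.69, 10.11), (0.0, 0.0)])
    def test_sewage_per_capita(self, kg_yr, g_day):
        pop = 5_000_000
        yearly, daily = sewage_per_capita(kg_yr * 1e3 * pop, pop)
        assert yearly == pytest.approx(kg_yr)
        assert daily == pytest.approx(g_day, abs=0.01)

    def test_biowaste_consolidation(self):
        components = {"wetorganic": 585.0, "park and garden": 178.0,
                      "wood": 769.0, "rubber": 64.0}
        total = biowaste_nitrogen(components, mixed_waste_kt=2762.0)
        assert total / 1e9 == pytest.approx(28.3, abs=0.1)

    def test_biowaste_edge_cases(self):
        assert biowaste_nitrogen({}) == 0.0
        assert biowaste_nitrogen({"x": 100.0}) / 1e9 == pytest.approx(0.95)


class TestEmissionsAccount:
    def test_total_scales_with_constant(self):
        acc = emissions_account({"traffic": 10e9, "industry": 5e9},
                                {"agriculture": 4e9}, year=2020)
        nox_n = sum(f.n_grams for f in acc.flows if f.label.startswith("NOx"))
        nh3_n = sum(f.n_grams for f in acc.flows if f.label.startswith("NH3"))
        assert nox_n == pytest.approx(0.44 * 15e9)
        assert nh3_n == pytest.approx(0.82 * 4e9)

    def test_empty_account(self):
        acc = emissions_account({}, {}, year=2020)
        assert acc.total("loss_to_air") == 0.0

    def test_headline_2020_split(self):
        # scaled so NOx-N is 12 Gg and NH3-N is 7.4 Gg
        acc = emissions_account({"all": 12e9 / 0.44}, {"all": 7.4e9 / 0.82}, 2020)
        assert acc.total("loss_to_air") / 1e9 == pytest.approx(12 + 7.4)


class TestCommodityAccounts:
    def test_fertilizer_identity_conversion(self, registry):
        s = AnnualSeries.from_observations("Fertilizer N", {2018: 102_400.0},
                                           element="domestic_supply", unit="t")
        accounts = commodity_sector_account([s], registry, "fertilizer")
        assert accounts[2018].total("domestic_supply") / 1e9 == pytest.approx(102.4)

    def test_forestry_volume_conversion(self, registry):
        s = AnnualSeries.from_observations("Industrial roundwood coniferous",
                                           {2018: 1e6}, element="production",
                                           unit="m3")
        accounts = commodity_sector_account([s], registry, "forestry")
        # 1 Mm3 conifer at 0.56 kg N/m3 -> 560 t N
        assert accounts[2018].total("production") / 1e6 == pytest.approx(560.0)

    def test_unresolvable_item_listed(self, registry):
        s = AnnualSeries.from_observations("Unobtainium", {2018: 1.0})
        with pytest.raises(KeyError, match="Unobtainium"):
            commodity_sector_account([s], registry, "mystery")

    def test_split_item_additivity(self, registry):
        whole = AnnualSeries.from_observations("Wheat", {2018: 1000.0},
                                               element="production", unit="t")
        half_a = AnnualSeries.from_observations("Wheat", {2018: 400.0},
                                                element="production", unit="t")
        half_b = AnnualSeries.from_observations("Barley", {2018: 600.0},
                                                element="production", unit="t")
        total_whole = commodity_sector_account([whole], registry, "food")[2018].total("production")
        total_split = commodity_sector_account([half_a, half_b], registry,
                                               "food")[2018].total("production")
        # different coefficients differ; same item split in two is identical
        again = commodity_sector_account(
            [AnnualSeries.from_observations("Wheat", {2018: 600.0},
                                            element="import", unit="t"),
             AnnualSeries.from_observations("Wheat", {2018: 400.0},
                                            element="production", unit="t")],
            registry, "food")[2018]
        assert again.total("production") + again.total("import") == pytest.approx(
            total_whole, rel=1e-12)
        assert total_split != total_whole

    def test_supply_identity_on_synthetic_data(self, registry):
        prod, imp, exp = 900.0, 300.0, 200.0
        series = [
            AnnualSeries.from_observations("Milk", {2018: q}, element=e, unit="t")
            for e, q in [("production", prod), ("import", imp), ("export", exp),
                         ("domestic_supply", prod + imp - exp)]
        ]
        acc = commodity_sector_account(series, registry, "dairy")[2018]
        lhs = acc.total("domestic_supply")
        rhs = acc.total("production") + acc.total("import") - acc.total("export")
        assert lhs == pytest.approx(rhs, rel=1e-9)

    def test_duplicate_label_rejected(self):
        acc = SectorAccount("x", 2018)
        acc.add("a", "production", 1.0)
        with pytest.raises(ValueError, match="duplicate"):
            acc.add("a", "production", 2.0)
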