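"""Synthetic-scenario generation: determinism, ground-truth recovery, rasters."""

import numpy as np
import pytest

from nbudget import synth
from nbudget.biomes import quantify_raster_areas
from nbudget.synth import (
    ScenarioSpec,
    generate_commodity_table,
    generate_full_scenario,
    generate_raster_fixture,
    run_pipeline,
)


def networks_equal(a, b, tol=0.0):
    fa, fb = a.to_frame(), b.to_frame()
    if len(fa) != len(fb):
        return False
    merged = fa.merge(fb, on=["source", "sink", "label"], suffixes=("_a", "_b"))
    if len(merged) != len(fa):
        return False
    return (merged.n_gg_a - merged.n_gg_b).abs().max() <= tol


class TestCommodityTables:
    def test_fao_dialect_columns(self):
        tables, _ = generate_commodity_table(ScenarioSpec(seed=1))
        for frame in tables.values():
            assert list(frame.columns) == ["Area", "Item", "Element", "Year",
                                           "Unit", "Value"]

    def test_gapless_tables_carry_every_year(self):
        spec = ScenarioSpec(seed=1, gap_fraction=0.0, tail_missing_years=0)
        tables, truth = generate_commodity_table(spec)
        n_rows = sum(len(f) for f in tables.values())
        assert n_rows == len(truth)

    def test_gaps_and_tail_are_inserted(self):
        spec = ScenarioSpec(seed=1, gap_fraction=0.2, tail_missing_years=3)
        tables, _ = generate_commodity_table(spec)
        fert = tables["fertilizer"]
        years = fert[fert.Element == "Production"]["Year"]
        assert years.max() == spec.years[1] - 3
        assert len(years) < spec.years[1] - 3 - spec.years[0] + 1  # interior gaps

    def test_invalid_gap_fraction_rejected(self):
        with pytest.raises(ValueError):
            ScenarioSpec(gap_fraction=1.0)


class TestRasterFixture:
    def test_counts_match_fractions_to_nearest_cell(self):
        grid = generate_raster_fixture(
            {"tundra": 0.617, "boreal": 0.317, "temperate": 0.067}, 40, 25, seed=5)
        out = quantify_raster_areas(grid)
        assert abs(out["tundra"]["cells"] - 617) <= 1
        assert abs(out["boreal"]["cells"] - 317) <= 1
        assert abs(out["temperate"]["cells"] - 66) <= 1
        assert sum(v["fraction"] for v in out.values()) == pytest.approx(1.0, abs=1e-9)

    def test_single_class_uniform(self):
        grid = generate_raster_fixture({"boreal": 1.0}, 10, 10, seed=0)
        assert (grid.cells == 1).all()

    def test_seeds_change_layout_not_counts(self):
        a = generate_raster_fixture({"a": 0.5, "b": 0.5}, 20, 20, seed=1)
        b = generate_raster_fixture({"a": 0.5, "b": 0.5}, 20, 20, seed=2)
        assert not (a.cells == b.cells).all()
        assert np.array_equal(np.bincount(a.cells.ravel()),
                              np.bincount(b.cells.ravel()))

    def test_impossible_fractions_rejected(self):
        with pytest.raises(ValueError, match="cell's worth"):
            generate_raster_fixture({"a": 0.5, "b": 0.6}, 10, 10, seed=0)


class TestGroundTruthRecovery:
    def test_gapless_scenario_recovers_exactly(self):
        spec = ScenarioSpec(seed=3, gap_fraction=0.0, tail_missing_years=0)
        bundle = generate_full_scenario(spec)
        assert networks_equal(run_pipeline(bundle), bundle["expected_network"],
                              tol=1e-9)

    def test_linear_trend_with_gaps_recovers_exactly(self):
        spec = ScenarioSpec(seed=7, gap_fraction=0.35, tail_missing_years=0)
        bundle = generate_full_scenario(spec)
        assert networks_equal(run_pipeline(bundle), bundle["expected_network"],
                              tol=1e-9)

    def test_curved_trend_error_is_bounded(self):
        # interpolating across a gap of width w on a trend with second
        # difference at most M errs by at most M * (w/2)^2
        spec = ScenarioSpec(seed=11, gap_fraction=0.3, tail_missing_years=0,
                            trend="curved")
        tables, truth = generate_commodity_table(spec)
        from nbudget.io import series_from_frame
        from nbudget.series import fill_series

        checked = 0
        for frame in tables.values():
            for s in series_from_frame(frame):
                repaired = fill_series(s)
                g = truth[(truth.item == s.item) & (truth.element == s.element)]
                tv = g.set_index("year")["value"]
                msd = np.max(np.abs(np.diff(tv.to_numpy(), 2)), initial=0.0)
                obs = repaired.observed_years
                for year, value in repaired.values.items():
                    if repaired.year_status(year) != "interpolated":
                        continue
                    width = (min(o for o in obs if o > year)
                             - max(o for o in obs if o < year))
                    bound = msd * (width / 2) ** 2 + 1e-9
                    assert abs(value - tv.loc[year]) <= bound
                    checked += 1
        assert checked > 0

    def test_zero_imbalance_means_zero_internal_residuals(self):
        bundle = generate_full_scenario(ScenarioSpec(seed=3, gap_fraction=0.0,
                                                     tail_missing_years=0))
        net = bundle["expected_network"]
        for pool, res in net.residuals().items():
            if net.pools[pool] == "internal":
                assert abs(res) <= 1e-9

    def test_injected_imbalance_lands_on_livestock(self):
        bundle = generate_full_scenario(ScenarioSpec(
            seed=3, gap_fraction=0.0, tail_missing_years=0,
            imbalance_injection_gg=5.0))
        net = bundle["expected_network"]
        assert net.pool_balance("livestock") == pytest.approx(5.0, abs=1e-9)
        others = [p for p, r in net.residuals().items()
                  if net.pools[p] == "internal" and p != "livestock"
                  and abs(r) > 1e-9]
        assert others == []


class TestDeterminism:
    def test_same_seed_identical_bundles(self):
        a = generate_full_scenario(ScenarioSpec(seed=11))
        b = generate_full_scenario(ScenarioSpec(seed=11))
        for sector in a["tables"]:
            assert a["tables"][sector].equals(b["tables"][sector])
        assert a["truth"].equals(b["truth"])
        assert np.array_equal(a["raster"].cells, b["raster"].cells)
        assert a["expected_network"].to_frame().equals(
            b["expected_network"].to_frame())

    def test_different_seeds_differ(self):
        a = generate_full_scenario(ScenarioSpec(seed=1, noise_sd=0.05))
        b = generate_full_scenario(ScenarioSpec(seed=2, noise_sd=0.05))
        assert not a["tables"]["food"].equals(b["tables"]["food"])
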