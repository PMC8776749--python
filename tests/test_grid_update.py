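"""Grid update: cell areas, ratio application, capping, yields."""

import numpy as np
import pandas as pd
import pytest

from cropgrid.grid_update import (
    AnnualInputs,
    CellFractionTable,
    apply_ratios,
    cap_annual_cell,
    compute_yield,
    run_annual_update,
)
from cropgrid.grids import CellAreaModel, Grid5Min, GridGeoreference, cell_area
from cropgrid.ratio_engine import ChangeRatioTable
from cropgrid.synthetic_data import recovery_check


def _geo(rows=6, cols=8, cellsize=5.0):
    return GridGeoreference(rows=rows, cols=cols, west=-180.0, north=90.0, cellsize=cellsize)


class TestCellArea:
    def test_equator_five_arcmin_cell(self):
        """Independent spherical computation: ~8.586 thousand ha."""
        geo = GridGeoreference.global_5min()
        equator_row = geo.rows // 2  # first row south of the equator
        assert cell_area(equator_row, geo) == pytest.approx(8.586343957, rel=1e-9)
        assert cell_area(equator_row - 1, geo) == pytest.approx(8.586343957, rel=1e-9)

    def test_symmetric_about_equator(self):
        geo = GridGeoreference.global_5min()
        rows = np.arange(geo.rows)
        a = cell_area(rows, geo)
        assert np.allclose(a, a[::-1], rtol=1e-12)

    def test_monotone_decrease_toward_poles(self):
        geo = GridGeoreference.global_5min()
        north_half = np.asarray(cell_area(np.arange(geo.rows // 2), geo))
        assert np.all(np.diff(north_half) > 0)  # grows toward the equator
        assert north_half[0] < north_half[-1]

    def test_model_grid_shape(self):
        model = CellAreaModel(_geo())
        assert model.as_grid().shape == (6, 8)
        assert model.area_of(0) == pytest.approx(cell_area(0, _geo()))


class TestApplyRatios:
    def _world(self):
        geo = _geo()
        h = Grid5Min.zeros(geo)
        h.values[2, 3] = 10.0
        fr = CellFractionTable(
            pd.DataFrame(
                {
                    "cell_row": [2, 2],
                    "cell_col": [3, 3],
                    "adm0_code": [1, 2],
                    "fraction": [0.6, 0.4],
                }
            )
        )
        ratios = ChangeRatioTable(crops=("Wheat",))
        return geo, h, fr, ratios

    def test_split_cell_blends_country_ratios(self):
        _, h, fr, ratios = self._world()
        ratios.set(1, "Wheat", 2.0, 2.0)
        ratios.set(2, "Wheat", 1.0, 1.0)
        out = apply_ratios(h, fr, ratios, "Wheat", "H")
        assert out.values[2, 3] == pytest.approx(16.0)

    def test_all_ratios_one_is_identity(self):
        _, h, fr, ratios = self._world()
        ratios.set(1, "Wheat", 1.0, 1.0)
        ratios.set(2, "Wheat", 1.0, 1.0)
        out = apply_ratios(h, fr, ratios, "Wheat", "H")
        assert np.array_equal(out.values, h.values)

    def test_coastal_cell_gets_full_country_ratio(self):
        """A cell 70% in one country (rest ocean) takes that country's
        ratio undiluted."""
        geo = _geo()
        h = Grid5Min.zeros(geo)
        h.values[1, 1] = 10.0
        fr = CellFractionTable(
            pd.DataFrame(
                {"cell_row": [1], "cell_col": [1], "adm0_code": [7], "fraction": [0.7]}
            )
        )
        ratios = ChangeRatioTable()
        ratios.set(7, "Wheat", 2.0, 2.0)
        out = apply_ratios(h, fr, ratios, "Wheat", "H")
        assert out.values[1, 1] == pytest.approx(20.0)

    def test_unknown_admin_unit_defaults_to_no_change(self, caplog):
        _, h, fr, ratios = self._world()
        ratios.set(1, "Wheat", 3.0, 3.0)  # unit 2 missing from the table
        with caplog.at_level("WARNING"):
            out = apply_ratios(h, fr, ratios, "Wheat", "H")
        assert out.values[2, 3] == pytest.approx(10 * (0.6 * 3.0 + 0.4 * 1.0))
        assert any("no change ratio" in r.message for r in caplog.records)

    def test_disputed_cells_unchanged(self, world, annual):
        """Cells of registry territories keep their 2010 values."""
        from cropgrid.synthetic_data import DISPUTED_ADM0, ISLAND_ADM0

        for code, cell in ((ISLAND_ADM0, (5, 5)), (DISPUTED_ADM0, (6, 60))):
            for (crop, mgmt), l2010 in world.harv_2010.items():
                new = annual.layers[("HarvArea", crop, mgmt)]
                assert new.values[cell] == l2010.values[cell], (code, crop, mgmt)


class TestAnnualCap:
    def test_proportional_reduction(self):
        out = cap_annual_cell({"a": 60.0, "b": 60.0}, 100.0)
        assert out == {"a": pytest.approx(49.5), "b": pytest.approx(49.5)}

    def test_under_budget_unchanged(self):
        areas = {"a": 30.0, "b": 20.0}
        assert cap_annual_cell(areas, 100.0) == areas

    def test_boundary_exactly_99_percent(self):
        areas = {"a": 99.0}
        assert cap_annual_cell(areas, 100.0) == areas

    def test_cap_preserves_crop_mix(self):
        out = cap_annual_cell({"a": 80.0, "b": 40.0}, 100.0)
        assert out["a"] / out["b"] == pytest.approx(2.0)
        assert sum(out.values()) == pytest.approx(99.0)


class TestYield:
    def _pair(self, p, h):
        geo = _geo(1, 1)
        return (
            Grid5Min(np.array([[p]]), np.zeros((1, 1), bool), geo),
            Grid5Min(np.array([[h]]), np.zeros((1, 1), bool), geo),
        )

    @pytest.mark.parametrize("p, h, y", [(6.0, 3.0, 2.0), (0.0, 0.0, 0.0), (0.0, 4.0, 0.0)])
    def test_yield_with_zero_rule(self, p, h, y):
        P, H = self._pair(p, h)
        assert compute_yield(P, H).values[0, 0] == y

    def test_grid_mismatch_rejected(self):
        P, _ = self._pair(1.0, 1.0)
        H = Grid5Min.zeros(_geo(2, 2))
        with pytest.raises(ValueError):
            compute_yield(P, H)


class TestRunAnnual:
    def test_conservation_without_cap(self, world, annual):
        """Country totals equal 2010 totals x the true ratio (oracle:
        the generator's arithmetic, no gridding involved)."""
        report = recovery_check(annual, world.truth, world.fractions, world.config.crops)
        assert report["exceeds_tol"].sum() == 0
        assert report["rel_error"].abs().max() < 1e-6

    def test_conservation_report_matches_truth(self, world, annual):
        merged = annual.conservation
        assert (merged["rel_error"].abs() < 1e-6).all()

    def test_cap_law_on_stressed_world(self, cap_world, cap_annual):
        geo = cap_world.geo
        areas = CellAreaModel(geo).as_grid()
        total = np.zeros((geo.rows, geo.cols))
        for (crop, mgmt) in cap_world.harv_2010:
            total += cap_annual.layers[("HarvArea", crop, mgmt)].values
        assert np.all(total <= 0.99 * areas + 1e-9)
        # the engineered cell was actually over budget before capping
        assert (cap_annual.cap_scale < 1).sum() >= 1

    def test_cap_shortfall_localized(self, cap_world, cap_annual):
        """Only the stressed country misses its target, only in area."""
        report = recovery_check(
            cap_annual, cap_world.truth, cap_world.fractions, cap_world.config.crops
        )
        flagged = report[report["exceeds_tol"]]
        assert not flagged.empty
        assert set(flagged["adm0_code"]) == {301}
        assert set(flagged["variable"]) == {"HarvArea"}
        assert (flagged["rel_error"] < 0).all()  # cap only removes area

    def test_production_yield_reconstruction(self, annual):
        """P = Y * H wherever H > 0 (1e-6 relative)."""
        for (var, crop, mgmt), layer in annual.layers.items():
            if var != "Yield":
                continue
            h = annual.layers[("HarvArea", crop, mgmt)].values
            p = annual.layers[("Production", crop, mgmt)].values
            grow = h > 0
            recon = layer.values[grow] * h[grow]
            assert np.allclose(recon, p[grow], rtol=1e-6)
            assert np.all(layer.values[~grow] == 0)

    def test_monotone_in_country_ratio(self):
        """Raising one country's rH never lowers any cell's area."""
        geo = _geo()
        h = Grid5Min.zeros(geo)
        h.values[:3, :4] = 5.0
        fr = CellFractionTable(
            pd.DataFrame(
                {
                    "cell_row": [0, 0, 1],
                    "cell_col": [0, 1, 1],
                    "adm0_code": [1, 1, 2],
                    "fraction": [1.0, 0.5, 1.0],
                }
            )
        )
        lo, hi = ChangeRatioTable(), ChangeRatioTable()
        lo.set(1, "Wheat", 1.0, 1.0); lo.set(2, "Wheat", 1.1, 1.1)
        hi.set(1, "Wheat", 1.5, 1.5); hi.set(2, "Wheat", 1.1, 1.1)
        out_lo = apply_ratios(h, fr, lo, "Wheat", "H")
        out_hi = apply_ratios(h, fr, hi, "Wheat", "H")
        assert np.all(out_hi.values >= out_lo.values - 1e-12)

    def test_shape_mismatch_aborts(self, world):
        from cropgrid.pipeline import ratio_table_for_bundle

        bad = dict(world.harv_2010)
        key = next(iter(bad))
        bad[key] = Grid5Min.zeros(_geo(4, 4))
        inputs = AnnualInputs(
            harv_2010=bad,
            prod_2010=world.prod_2010,
            fractions=world.fractions,
            ratios=ratio_table_for_bundle(world),
        )
        with pytest.raises(ValueError, match="mismatch"):
            run_annual_update(inputs)
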