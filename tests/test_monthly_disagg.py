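"""Monthly disaggregation: subcrop scaling, donors, ordered truncation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cropgrid.concordance import MircaMatch, load_mirca_matches
from cropgrid.grids import CellAreaModel, Grid5Min, GridGeoreference
from cropgrid.monthly_disagg import (
    NoDonorCalendarError,
    SubcropCalendar,
    SubcropEntry,
    cap_monthly_cell,
    find_nearest_source_cell,
    mirca_annual_harvested_area,
    run_monthly,
    scale_subcrops,
    season_months,
)


def _geo(rows=8, cols=12):
    return GridGeoreference(rows=rows, cols=cols, west=-180.0, north=90.0, cellsize=5.0)


class TestCalendarBasics:
    def test_annual_area_sums_subcrops(self):
        cal = SubcropCalendar()
        cal.add(1, 1, "Rice", "Rainfed", 1, 3, 6.0)
        cal.add(1, 1, "Rice", "Rainfed", 6, 8, 4.0)
        assert mirca_annual_harvested_area(cal, 1, 1, "Rice", "Rainfed") == 10.0
        assert mirca_annual_harvested_area(cal, 2, 2, "Rice", "Rainfed") == 0.0
        cal2 = SubcropCalendar()
        cal2.add(0, 0, "Wheat", "Irrigated", 4, 9, 7.0)
        assert mirca_annual_harvested_area(cal2, 0, 0, "Wheat", "Irrigated") == 7.0

    def test_pooling_over_two_mirca_crops(self):
        cal = SubcropCalendar()
        cal.add(1, 1, "Rye", "Rainfed", 1, 4, 3.0)
        cal.add(1, 1, "Millet", "Rainfed", 6, 9, 7.0)
        assert mirca_annual_harvested_area(cal, 1, 1, ("Rye", "Millet"), "Rainfed") == 10.0

    def test_subcrop_limit_enforced(self):
        cal = SubcropCalendar()
        for _ in range(5):
            cal.add(0, 0, "Rice", "Rainfed", 1, 2, 1.0)
        with pytest.raises(ValueError, match="subcrops"):
            cal.add(0, 0, "Rice", "Rainfed", 1, 2, 1.0)

    def test_round_trip_csv(self, tmp_path):
        cal = SubcropCalendar()
        cal.add(1, 2, "Rice", "Rainfed", 11, 2, 6.5)
        cal.add(3, 4, "Wheat", "Irrigated", 4, 9, 1.25)
        p = tmp_path / "cal.csv"
        cal.write_csv(p)
        back = SubcropCalendar.read_csv(p)
        assert back.entries(1, 2, "Rice", "Rainfed") == cal.entries(1, 2, "Rice", "Rainfed")
        assert back.entries(3, 4, "Wheat", "Irrigated") == cal.entries(3, 4, "Wheat", "Irrigated")


class TestSeasonsAndScaling:
    def test_wrap_season_occupies_both_ends(self):
        assert season_months(11, 2) == [11, 12, 1, 2]
        assert season_months(4, 9) == [4, 5, 6, 7, 8, 9]
        assert season_months(6, 6) == [6]

    def test_two_subcrop_scaling(self):
        entries = [SubcropEntry(1, 3, 6.0), SubcropEntry(6, 8, 4.0)]
        scaled, monthly = scale_subcrops(20.0, entries)
        assert scaled == [pytest.approx(12.0), pytest.approx(8.0)]
        assert monthly[1] == pytest.approx(12.0)  # February
        assert monthly[6] == pytest.approx(8.0)  # July
        assert monthly[4] == 0.0  # May fallow

    def test_single_subcrop_carries_full_annual_area(self):
        scaled, monthly = scale_subcrops(13.0, [SubcropEntry(4, 9, 2.0)])
        assert scaled == [13.0]
        assert np.all(monthly[3:9] == 13.0)
        assert np.all(monthly[[0, 1, 2, 9, 10, 11]] == 0.0)

    def test_wrap_season_scaling(self):
        _, monthly = scale_subcrops(8.0, [SubcropEntry(11, 2, 5.0)])
        assert np.all(monthly[[10, 11, 0, 1]] == 8.0)
        assert np.all(monthly[2:10] == 0.0)

    def test_empty_calendar_requires_donor(self):
        with pytest.raises(NoDonorCalendarError):
            scale_subcrops(5.0, [])


class TestNearestDonor:
    def test_cell_with_own_calendar_returns_itself(self):
        occ = np.array([[2, 3], [5, 5]])
        assert find_nearest_source_cell(occ, 2, 3, _geo()) == (2, 3)

    def test_nearer_candidate_wins(self):
        occ = np.array([[0, 1], [0, 10]])
        assert find_nearest_source_cell(occ, 0, 2, _geo(4, 24)) == (0, 1)

    def test_equidistant_tie_breaks_to_lower_row_col(self):
        """Exhaustive-scan oracle on a symmetric layout."""
        geo = _geo(9, 12)
        # same row, symmetric columns around col 5 -> identical distances
        occ = np.array([[4, 3], [4, 7]])
        assert find_nearest_source_cell(occ, 4, 5, geo) == (4, 3)
        # symmetric rows on one column (grid symmetric about equator row)
        occ2 = np.array([[3, 6], [5, 6]])
        got = find_nearest_source_cell(occ2, 4, 6, geo)
        assert got == (3, 6)

    def test_empty_occupancy_raises(self):
        with pytest.raises(NoDonorCalendarError):
            find_nearest_source_cell(np.empty((0, 2), dtype=int), 0, 0, _geo())

    def test_matches_exhaustive_scan(self):
        """Random occupancy: agrees with a brute-force haversine loop."""
        rng = np.random.default_rng(5)
        geo = _geo(10, 20)
        occ = np.unique(rng.integers(0, [10, 20], size=(15, 2)), axis=0)

        def brute(r, c):
            def dist(cell):
                la1, lo1 = np.deg2rad(geo.lat_center(r)), np.deg2rad(geo.lon_center(c))
                la2, lo2 = np.deg2rad(geo.lat_center(cell[0])), np.deg2rad(geo.lon_center(cell[1]))
                h = np.sin((la2 - la1) / 2) ** 2 + np.cos(la1) * np.cos(la2) * np.sin((lo2 - lo1) / 2) ** 2
                return 2 * np.arcsin(min(1.0, np.sqrt(h)))

            return min(map(tuple, occ), key=lambda cell: (round(dist(cell), 12), cell))

        for r, c in rng.integers(0, [10, 20], size=(20, 2)):
            assert find_nearest_source_cell(occ, r, c, geo) == brute(r, c)


ORDERS = {"Stimulants": 1, "Cotton": 4, "Rice": 19, "Wheat": 21}


class TestMonthlyCap:
    def test_rainfed_removed_before_irrigated(self):
        areas = {
            ("Stimulants", "Rainfed"): 10.0,
            ("Wheat", "Rainfed"): 60.0,
            ("Wheat", "Irrigated"): 40.0,
        }
        out, removed = cap_monthly_cell(areas, 100.0, ORDERS)
        assert out[("Stimulants", "Rainfed")] == 0.0
        assert out[("Wheat", "Rainfed")] == pytest.approx(59.0)
        assert out[("Wheat", "Irrigated")] == 40.0  # untouched
        assert removed == pytest.approx(11.0)

    def test_under_budget_no_removal(self):
        areas = {("Rice", "Rainfed"): 95.0}
        out, removed = cap_monthly_cell(areas, 100.0, ORDERS)
        assert out == areas and removed == 0.0

    def test_partial_reduction_of_single_crop(self):
        areas = {("Stimulants", "Rainfed"): 99.5}
        out, removed = cap_monthly_cell(areas, 100.0, ORDERS)
        assert out[("Stimulants", "Rainfed")] == pytest.approx(99.0)
        assert removed == pytest.approx(0.5)

    def test_irrigated_touched_only_after_rainfed_exhausted(self):
        areas = {
            ("Rice", "Rainfed"): 30.0,
            ("Wheat", "Irrigated"): 120.0,
        }
        out, removed = cap_monthly_cell(areas, 100.0, ORDERS)
        assert out[("Rice", "Rainfed")] == 0.0
        assert out[("Wheat", "Irrigated")] == pytest.approx(99.0)
        assert removed == pytest.approx(51.0)

    @staticmethod
    def _oracle(areas, cell_area, orders, cap=0.99):
        """Independent greedy reference: explicit removal queue."""
        budget = cap * cell_area
        excess = sum(areas.values()) - budget
        out = dict(areas)
        if excess <= 0:
            return out, 0.0
        queue = sorted(
            (k for k in out if k[1] == "Rainfed"), key=lambda k: (orders[k[0]], k[0])
        ) + sorted(
            (k for k in out if k[1] == "Irrigated"), key=lambda k: (orders[k[0]], k[0])
        )
        removed = 0.0
        for k in queue:
            if excess <= 0:
                break
            take = min(out[k], excess)
            out[k] -= take
            removed += take
            excess -= take
        return out, removed

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.data())
    def test_matches_greedy_oracle(self, data):
        crops = list(ORDERS)
        keys = [
            (c, m)
            for c in crops
            for m in ("Rainfed", "Irrigated")
            if data.draw(st.booleans(), label=f"use {c} {m}")
        ]
        areas = {
            k: data.draw(st.floats(0, 60), label=f"area {k}") for k in keys
        }
        cell = data.draw(st.floats(10, 120), label="cell_area")
        got, got_removed = cap_monthly_cell(areas, cell, ORDERS)
        exp, exp_removed = self._oracle(areas, cell, ORDERS)
        assert got_removed == pytest.approx(exp_removed, abs=1e-9)
        for k in areas:
            assert got[k] == pytest.approx(exp[k], abs=1e-9)
        assert sum(got.values()) <= 0.99 * cell + 1e-9
        # truncation never increases an area
        assert all(got[k] <= areas[k] + 1e-12 for k in areas)


class TestRunMonthly:
    def test_subcrop_sum_equals_annual(self, world, annual, monthly):
        """Pre-truncation identity: per-subcrop constant areas sum to the
        annual harvested area in every growing cell (1e-9 relative)."""
        for (crop, mgmt), cube in monthly.cubes.items():
            h = annual.layers[("HarvArea", crop, mgmt)].values
            per_subcrop_area = cube.data.max(axis=1)  # constant over season
            total = per_subcrop_area.sum(axis=0)
            grow = h > 0
            assert np.allclose(total[grow], h[grow], rtol=1e-9), (crop, mgmt)
            assert np.all(total[~grow] == 0)

    def test_two_season_rice_is_bimodal(self, monthly):
        """Two rice subcrops in disjoint seasons -> two peaks with a dip."""
        series = sum(
            cube.global_series()
            for (crop, _), cube in monthly.cubes.items()
            if crop == "Rice"
        )
        # seasons are Feb-May and Jul-Oct; Jun and Dec-Jan are fallow
        assert series[2] > 0 and series[8] > 0
        assert series[5] < series[2] and series[5] < series[8]
        assert series[11] == 0.0

    def test_borrowed_calendars_match_truth_donors(self, world, annual, monthly):
        """Every calendar-less growing cell borrowed from the donor the
        generator found with its own exhaustive scan."""
        truth = world.truth.donor_map
        assert truth  # the world does have calendar gaps
        got = {
            (r.gaez_crop, r.management, r.cell_row, r.cell_col): (r.donor_row, r.donor_col)
            for r in monthly.donor_distances.itertuples(index=False)
        }
        assert got == truth

    def test_no_monthly_product_for_empty_layer(self, world):
        """A crop x management with zero area everywhere emits no cube."""
        geo = world.geo
        empty = Grid5Min.zeros(geo)
        res = run_monthly(
            {("Cassava", "Irrigated"): empty}, world.calendar, world.matches
        )
        assert res.cubes == {}

    def test_monthly_cap_by_removal_order(self):
        """Overloaded cell-month: low-priority rainfed crops vanish first,
        irrigated survives, budget holds afterwards."""
        geo = _geo(4, 4)
        areas = CellAreaModel(geo).as_grid()
        big = areas[1, 1]  # one cell's worth
        layers = {}
        cal = SubcropCalendar()
        for crop, mgmt, frac in (
            ("Stimulants", "Rainfed", 0.30),
            ("Wheat", "Rainfed", 0.50),
            ("Wheat", "Irrigated", 0.40),
        ):
            g = Grid5Min.zeros(geo)
            g.values[1, 1] = frac * big
            layers[(crop, mgmt)] = g
            mirca = "Others_annual" if crop == "Stimulants" else "Wheat"
            cal.add(1, 1, mirca, mgmt, 4, 9, 1.0)
        res = run_monthly(layers, cal, load_mirca_matches())
        month = 5  # June, inside the shared season
        stim = res.cubes[("Stimulants", "Rainfed")].monthly_totals()[month, 1, 1]
        wr = res.cubes[("Wheat", "Rainfed")].monthly_totals()[month, 1, 1]
        wi = res.cubes[("Wheat", "Irrigated")].monthly_totals()[month, 1, 1]
        # excess 0.21*big comes entirely out of the order-1 crop
        assert stim == pytest.approx((0.30 - 0.21) * big)
        assert wr == pytest.approx(0.50 * big)  # higher order: untouched
        assert wi == pytest.approx(0.40 * big)  # irrigated untouched
        assert stim + wr + wi <= 0.99 * big + 1e-9
        assert res.max_removed_1000ha > 0
        assert 0 < res.max_removed_share < 1

    def test_post_cap_budget_everywhere(self, world, monthly):
        areas = CellAreaModel(world.geo).as_grid()
        total = sum(c.monthly_totals() for c in monthly.cubes.values())
        assert np.all(total <= 0.99 * areas[None, :, :] + 1e-9)

    def test_crop_without_any_calendar_raises(self):
        geo = _geo(3, 3)
        g = Grid5Min.zeros(geo)
        g.values[0, 0] = 1.0
        with pytest.raises(NoDonorCalendarError):
            run_monthly({("Barley", "Rainfed"): g}, SubcropCalendar(), load_mirca_matches())
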