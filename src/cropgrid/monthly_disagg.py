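"""Monthly physical cropland area from annual harvested area.

Annual harvested area counts every harvest, so a double-cropped hectare
counts twice; physical area counts the land once per month it is occupied.
MIRCA2000-style crop calendars bridge the two: each crop in a cell carries
up to five "subcrops", season-specific components with their own planting
and harvest months and physical area A_M,n.  With H_M = sum_n A_M,n the
calendar's annual harvested area, a cell's updated annual harvested area
H_G is spread over months as

    A_G(month) = sum_n (A_M,n / H_M) * H_G   over subcrops growing that month

so each subcrop keeps a constant physical area across its growing season
and the subcrop areas sum to H_G.  Cells that grow a crop in the updated
annual layer but have no calendar for the matched MIRCA crop borrow the
calendar of the nearest (great-circle) cell that has one, within the same
management.  Finally, for each month independently, if the cell's total
cropland exceeds 99% of the cell area, area is removed crop by crop in
removal-order priority — all rainfed crops (ascending order) before any
irrigated crop — zeroing each crop in turn and partially reducing the last
one touched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .concordance import MircaMatch
from .grids import CellAreaModel, Grid5Min, GridGeoreference

__all__ = [
    "SubcropEntry",
    "SubcropCalendar",
    "MonthlyCube",
    "MonthlyResult",
    "season_months",
    "mirca_annual_harvested_area",
    "scale_subcrops",
    "find_nearest_source_cell",
    "cap_monthly_cell",
    "run_monthly",
    "NoDonorCalendarError",
    "MAX_SUBCROPS",
]

logger = logging.getLogger(__name__)

MAX_SUBCROPS = 5


class NoDonorCalendarError(RuntimeError):
    """A crop has updated area somewhere but no calendar exists anywhere."""


def season_months(start: int, end: int) -> list[int]:
    """Months occupied by a season; planting after harvest wraps December.

    e.g. (4, 9) -> [4..9]; (11, 2) -> [11, 12, 1, 2].
    """
    if not (1 <= start <= 12 and 1 <= end <= 12):
        raise ValueError(f"months must be in 1..12, got {start}..{end}")
    if start <= end:
        return list(range(start, end + 1))
    return list(range(start, 13)) + list(range(1, end + 1))


@dataclass(frozen=True)
class SubcropEntry:
    """One subcrop's season and physical area (1000 ha, constant over the
    season)."""

    start_month: int
    end_month: int
    area: float

    def months(self) -> list[int]:
        return season_months(self.start_month, self.end_month)


class SubcropCalendar:
    """Per (cell, MIRCA crop, management) lists of subcrop entries."""

    def __init__(self) -> None:
        self._entries: dict[tuple[int, int, str, str], list[SubcropEntry]] = {}

    def add(
        self,
        row: int,
        col: int,
        mirca_crop: str,
        management: str,
        start_month: int,
        end_month: int,
        area: float,
    ) -> None:
        if area < 0:
            raise ValueError("subcrop area must be >= 0")
        key = (int(row), int(col), mirca_crop, management)
        lst = self._entries.setdefault(key, [])
        if len(lst) >= MAX_SUBCROPS:
            raise ValueError(
                f"more than {MAX_SUBCROPS} subcrops for {mirca_crop} at {(row, col)}"
            )
        lst.append(SubcropEntry(int(start_month), int(end_month), float(area)))

    def entries(
        self, row: int, col: int, mirca_crops: tuple[str, ...] | str, management: str
    ) -> list[SubcropEntry]:
        """Subcrop entries pooled over one or more MIRCA crops."""
        if isinstance(mirca_crops, str):
            mirca_crops = (mirca_crops,)
        out: list[SubcropEntry] = []
        for mc in mirca_crops:
            out.extend(self._entries.get((int(row), int(col), mc, management), []))
        return out

    def occupied_cells(
        self, mirca_crops: tuple[str, ...] | str, management: str
    ) -> np.ndarray:
        """(n, 2) array of (row, col) cells where pooled H_M > 0, sorted."""
        if isinstance(mirca_crops, str):
            mirca_crops = (mirca_crops,)
        cells: dict[tuple[int, int], float] = {}
        for (r, c, mc, mg), lst in self._entries.items():
            if mg == management and mc in mirca_crops:
                cells[(r, c)] = cells.get((r, c), 0.0) + sum(e.area for e in lst)
        occ = sorted(k for k, v in cells.items() if v > 0)
        return np.array(occ, dtype=int).reshape(-1, 2)

    @classmethod
    def read_csv(cls, path) -> "SubcropCalendar":
        """Columns: cell_row, cell_col, mirca_crop, management, subcrop,
        start_month, end_month, area."""
        df = pd.read_csv(path)
        cal = cls()
        for rec in df.itertuples(index=False):
            cal.add(
                rec.cell_row, rec.cell_col, str(rec.mirca_crop),
                str(rec.management), rec.start_month, rec.end_month, rec.area,
            )
        return cal

    def write_csv(self, path) -> None:
        recs = []
        for (r, c, mc, mg), lst in sorted(self._entries.items()):
            for n, e in enumerate(lst, start=1):
                recs.append(
                    {
                        "cell_row": r, "cell_col": c, "mirca_crop": mc,
                        "management": mg, "subcrop": n,
                        "start_month": e.start_month, "end_month": e.end_month,
                        "area": e.area,
                    }
                )
        pd.DataFrame(
            recs,
            columns=[
                "cell_row", "cell_col", "mirca_crop", "management",
                "subcrop", "start_month", "end_month", "area",
            ],
        ).to_csv(path, index=False)


def mirca_annual_harvested_area(
    calendar: SubcropCalendar,
    row: int,
    col: int,
    mirca_crops: tuple[str, ...] | str,
    management: str,
) -> float:
    """H_M: annual harvested area implied by the calendar at one cell
    (sum of subcrop areas; 0 if the crop is absent)."""
    return sum(e.area for e in calendar.entries(row, col, mirca_crops, management))


def scale_subcrops(
    h_g: float, entries: list[SubcropEntry]
) -> tuple[list[float], np.ndarray]:
    """Scale a calendar's subcrops so they carry H_G instead of H_M.

    Returns (per-subcrop scaled areas, 12-vector of monthly crop totals).
    Subcrop n carries (A_M,n / H_M) * H_G in each of its growing months;
    a single subcrop therefore carries exactly H_G.  Raises if the
    calendar is empty (H_M = 0) — callers must first borrow a donor cell.
    """
    h_m = sum(e.area for e in entries)
    if h_m <= 0:
        raise NoDonorCalendarError("no calendar (H_M = 0); nearest-cell fallback required")
    scaled = [e.area / h_m * h_g for e in entries]
    monthly = np.zeros(12)
    for e, a in zip(entries, scaled):
        for m in e.months():
            monthly[m - 1] += a
    return scaled, monthly


def find_nearest_source_cell(
    occupied: np.ndarray, row: int, col: int, geo: GridGeoreference
) -> tuple[int, int]:
    """Great-circle-nearest cell (by center) among ``occupied``.

    ``occupied`` is an (n, 2) array of (row, col).  Ties break on
    (row, col) order.  A cell that is itself occupied returns itself.
    """
    if occupied.size == 0:
        raise NoDonorCalendarError("crop has no calendar anywhere on the grid")
    rows = occupied[:, 0]
    cols = occupied[:, 1]
    lat1 = np.deg2rad(geo.lat_center(row))
    lon1 = np.deg2rad(geo.lon_center(col))
    lat2 = np.deg2rad(geo.lat_center(rows))
    lon2 = np.deg2rad(geo.lon_center(cols))
    # haversine central angle; radius irrelevant for argmin but kept exact
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    d = 2 * np.arcsin(np.minimum(1.0, np.sqrt(a)))
    # lexicographic tie-break: occupied is sorted, argmin takes the first
    # index attaining the minimum, i.e. lowest (row, col)
    best = int(np.argmin(np.round(d, decimals=12)))
    return int(rows[best]), int(cols[best])


def cap_monthly_cell(
    month_areas: dict[tuple[str, str], float],
    cell_area: float,
    orders: dict[str, int],
    cap_fraction: float = 0.99,
) -> tuple[dict[tuple[str, str], float], float]:
    """Truncate one cell-month to the 99% budget by removal order.

    ``month_areas`` maps (GAEZ crop, management) to physical area.  Area
    is removed crop by crop — every rainfed crop in ascending removal
    order (ties alphabetical), then every irrigated crop likewise —
    zeroing each crop until the remaining excess fits, with the last crop
    touched reduced partially.  Returns (truncated areas, total removed).
    """
    for v in month_areas.values():
        if v < 0:
            raise ValueError("areas must be >= 0")
    total = sum(month_areas.values())
    budget = cap_fraction * cell_area
    out = dict(month_areas)
    if total <= budget:
        return out, 0.0
    excess = total - budget
    removed = 0.0

    def sort_key(item):
        (crop, mgmt), _ = item
        return (orders.get(crop, 0), crop)

    rainfed = sorted(
        ((k, v) for k, v in out.items() if k[1] == "Rainfed"), key=sort_key
    )
    irrigated = sorted(
        ((k, v) for k, v in out.items() if k[1] == "Irrigated"), key=sort_key
    )
    for key, area in rainfed + irrigated:
        if excess <= 0:
            break
        take = min(area, excess)
        out[key] = area - take
        removed += take
        excess -= take
    return out, removed


@dataclass
class MonthlyCube:
    """12-month physical-area stack for one crop x management.

    ``data`` has shape (MAX_SUBCROPS, 12, rows, cols) in 1000 ha; unused
    subcrop slots are zero.  Before truncation each subcrop's area is
    constant over its growing months; the independent per-month cap may
    break that constancy.
    """

    crop: str
    management: str
    data: np.ndarray
    geo: GridGeoreference

    def monthly_totals(self) -> np.ndarray:
        """(12, rows, cols) summed over subcrops."""
        return self.data.sum(axis=0)

    def global_series(self) -> np.ndarray:
        """12-vector of global totals (1000 ha)."""
        return self.data.sum(axis=(0, 2, 3))

    def n_subcrops(self) -> int:
        used = np.nonzero(self.data.sum(axis=(1, 2, 3)))[0]
        return int(used[-1]) + 1 if used.size else 0


@dataclass
class MonthlyResult:
    """Monthly cubes plus the truncation report."""

    cubes: dict[tuple[str, str], MonthlyCube]
    removed_by_month: np.ndarray
    max_removed_1000ha: float
    max_removed_share: float
    donor_distances: pd.DataFrame = field(default_factory=pd.DataFrame)


def run_monthly(
    annual_harv: dict[tuple[str, str], Grid5Min],
    calendar: SubcropCalendar,
    matches: dict[str, MircaMatch],
    cap_fraction: float = 0.99,
) -> MonthlyResult:
    """Disaggregate updated annual harvested area into monthly cubes.

    For each (crop, management) with a nonzero annual layer: look up the
    matched MIRCA crop's calendar in each growing cell (multi-match crops
    pool the subcrop lists of both MIRCA crops), borrowing the nearest
    same-management calendar where the cell has none; scale subcrops so
    they sum to the annual harvested area; then apply the per-month
    removal-order cap across all crops.  All-zero layers (e.g. irrigated
    cassava) produce no cube.
    """
    geo = next(iter(annual_harv.values())).geo
    areas = CellAreaModel(geo).as_grid()
    orders = {g: m.removal_order for g, m in matches.items()}

    cubes: dict[tuple[str, str], MonthlyCube] = {}
    donor_recs: list[dict] = []
    for (crop, mgmt), layer in sorted(annual_harv.items()):
        if layer.geo != geo:
            raise ValueError("annual layers on different grids")
        grow = np.argwhere((layer.values > 0) & ~layer.mask)
        if grow.size == 0:
            continue  # nothing planted: emit no monthly product
        match = matches[crop]
        occupied = calendar.occupied_cells(match.mirca_crops, mgmt)
        data = np.zeros((MAX_SUBCROPS, 12, geo.rows, geo.cols))
        for r, c in grow:
            entries = calendar.entries(r, c, match.mirca_crops, mgmt)
            if sum(e.area for e in entries) <= 0:
                dr, dc = find_nearest_source_cell(occupied, r, c, geo)
                entries = calendar.entries(dr, dc, match.mirca_crops, mgmt)
                donor_recs.append(
                    {
                        "gaez_crop": crop, "management": mgmt,
                        "cell_row": int(r), "cell_col": int(c),
                        "donor_row": dr, "donor_col": dc,
                    }
                )
            if len(entries) > MAX_SUBCROPS:
                raise ValueError(
                    f"pooled calendar for {crop} at {(int(r), int(c))} has "
                    f"{len(entries)} subcrops (> {MAX_SUBCROPS})"
                )
            scaled, _ = scale_subcrops(float(layer.values[r, c]), entries)
            for n, (e, a) in enumerate(zip(entries, scaled)):
                for m in e.months():
                    data[n, m - 1, r, c] = a
        cubes[(crop, mgmt)] = MonthlyCube(crop, mgmt, data, geo)

    removed_by_month = _apply_monthly_cap(cubes, areas, orders, cap_fraction, geo)

    if cubes:
        post_cap = np.sum([c.global_series() for c in cubes.values()], axis=0)
        pre_cap_max = float((post_cap + removed_by_month).max())
    else:
        pre_cap_max = 0.0
    max_removed = float(removed_by_month.max())
    share = max_removed / pre_cap_max if pre_cap_max > 0 else 0.0
    return MonthlyResult(
        cubes=cubes,
        removed_by_month=removed_by_month,
        max_removed_1000ha=max_removed,
        max_removed_share=share,
        donor_distances=pd.DataFrame(donor_recs),
    )


def _apply_monthly_cap(
    cubes: dict[tuple[str, str], MonthlyCube],
    areas: np.ndarray,
    orders: dict[str, int],
    cap_fraction: float,
    geo: GridGeoreference,
) -> np.ndarray:
    """Per cell-month removal-order truncation, applied in place.

    Removal is resolved at crop level; all subcrops of a reduced crop are
    scaled by the crop's post-removal fraction in that month.
    """
    removed_by_month = np.zeros(12)
    if not cubes:
        return removed_by_month
    keys = list(cubes)
    totals = np.stack([cubes[k].monthly_totals() for k in keys])  # (K, 12, R, C)
    grand = totals.sum(axis=0)
    budget = cap_fraction * areas[None, :, :]
    over = np.argwhere(grand > budget + 1e-12)
    for m, r, c in over:
        month_areas = {k: float(totals[i, m, r, c]) for i, k in enumerate(keys)}
        capped, removed = cap_monthly_cell(
            month_areas, float(areas[r, c]), orders, cap_fraction
        )
        removed_by_month[m] += removed
        for i, k in enumerate(keys):
            before = month_areas[k]
            if before <= 0:
                continue
            frac = capped[k] / before
            if frac < 1:
                cubes[k].data[:, m, r, c] *= frac
    return removed_by_month
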