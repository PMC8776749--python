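"""Validation machinery: zonal aggregation, regression diagnostics,
harvested-area reports and cropland-extent bounds.

The pipeline's outputs are checked the way gridded cropland products are
usually evaluated: sum layers over spatial zones (administrative units or
hydrologic basins), regress one product's zone totals on another's, and
bound the physical cropland extent between the maximum-reuse and
minimum-reuse assumptions about multi-cropping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .grids import CellAreaModel, Grid5Min, GridGeoreference
from .grid_update import CellFractionTable
from .ratio_engine import three_year_mean

__all__ = [
    "ZoneMap",
    "ComparisonStats",
    "zonal_sum",
    "compare_tables",
    "cropland_extent_bounds",
    "harvested_area_report",
]

UNZONED = -1


@dataclass
class ZoneMap:
    """Per-cell integer zone identifier; UNZONED (-1) marks cells outside
    every zone."""

    zones: np.ndarray
    labels: dict[int, str] | None = None

    def __post_init__(self) -> None:
        self.zones = np.asarray(self.zones, dtype=int)

    @classmethod
    def from_fractions(cls, fractions: CellFractionTable, geo: GridGeoreference) -> "ZoneMap":
        """Zone map assigning each cell to its largest-fraction admin unit."""
        t = fractions.table.sort_values("fraction", ascending=False)
        t = t.drop_duplicates(["cell_row", "cell_col"])
        z = np.full((geo.rows, geo.cols), UNZONED, dtype=int)
        z[t["cell_row"].to_numpy(), t["cell_col"].to_numpy()] = t["adm0_code"].to_numpy()
        return cls(z)


def zonal_sum(layer: Grid5Min, zones: ZoneMap) -> tuple[dict[int, float], float]:
    """Exact per-zone totals of a layer; returns (totals, unzoned total).

    No-data cells contribute nowhere; cells with zone UNZONED are summed
    separately so mass is conserved:
    sum(totals) + unzoned == global masked total.
    """
    z = zones.zones
    if z.shape != layer.values.shape:
        raise ValueError("zone map and layer shapes differ")
    valid = ~layer.mask
    vals = layer.values[valid]
    zs = z[valid]
    unzoned = float(vals[zs == UNZONED].sum())
    sel = zs != UNZONED
    totals_ser = pd.Series(vals[sel]).groupby(zs[sel]).sum()
    return {int(k): float(v) for k, v in totals_ser.items()}, unzoned


@dataclass(frozen=True)
class ComparisonStats:
    """OLS diagnostics of paired zone totals: a regressed on b."""

    r2: float
    slope: float
    intercept: float
    rmse: float
    n_zones: int


def compare_tables(a: dict[int, float], b: dict[int, float]) -> ComparisonStats:
    """Ordinary least squares of a's zone totals on b's, with intercept.

    A slope below 1 means ``a`` under-reports relative to ``b``.  RMSE is
    the root-mean-square regression residual in the tables' units.
    """
    shared = sorted(set(a) & set(b))
    if len(shared) < 2:
        raise ValueError("need at least 2 shared zones to regress")
    ya = np.array([a[z] for z in shared], dtype=float)
    xb = np.array([b[z] for z in shared], dtype=float)
    if np.allclose(xb, xb[0]):
        raise ValueError("degenerate regressor: all zone totals equal")
    res = stats.linregress(xb, ya)
    resid = ya - (res.intercept + res.slope * xb)
    return ComparisonStats(
        r2=float(res.rvalue**2),
        slope=float(res.slope),
        intercept=float(res.intercept),
        rmse=float(np.sqrt(np.mean(resid**2))),
        n_zones=len(shared),
    )


def cropland_extent_bounds(
    monthly_totals: list[np.ndarray],
    annual_harv: list[Grid5Min],
    geo: GridGeoreference,
) -> tuple[Grid5Min, Grid5Min]:
    """Bounds on physical cropland extent per cell (1000 ha).

    Minimum extent assumes maximum re-use of land by multi-cropping: the
    largest monthly total over all crops.  Maximum extent assumes no
    re-use: the annual harvested-area total, capped by the cell's area.
    ``monthly_totals`` are (12, rows, cols) stacks per crop/management.
    """
    areas = CellAreaModel(geo).as_grid()
    if monthly_totals:
        month_sum = np.zeros((12, geo.rows, geo.cols))
        for m in monthly_totals:
            month_sum += np.asarray(m)
        min_extent = month_sum.max(axis=0)
    else:
        min_extent = np.zeros((geo.rows, geo.cols))
    annual_sum = np.zeros((geo.rows, geo.cols))
    mask = np.ones((geo.rows, geo.cols), bool)
    for layer in annual_harv:
        annual_sum += layer.values
        mask &= layer.mask
    max_extent = np.minimum(annual_sum, areas)
    # multi-cropping cannot push the instantaneous area above the annual sum
    min_extent = np.minimum(min_extent, max_extent)
    return (
        Grid5Min(np.where(mask, 0, min_extent), mask, geo),
        Grid5Min(np.where(mask, 0, max_extent), mask, geo),
    )


def harvested_area_report(
    harv_layers: dict[tuple[str, str], Grid5Min],
    faostat: pd.DataFrame,
    concordance,
    by: str = "crop",
    fractions: CellFractionTable | None = None,
) -> pd.DataFrame:
    """Compare gridded 2015 harvested area against the reported statistics.

    ``by="crop"``: one row per GAEZ crop, gridded global total vs the
    2014-2016 mean of the reported harvested area summed over countries
    (columns: gridded_1000ha, statistic_1000ha, difference_1000ha,
    difference_pct), sorted by gridded total descending.  ``by="country"``
    sums all crops per admin unit instead (requires ``fractions``).
    Differences smaller than 1% are rounded to one significant figure in
    ``difference_pct_label``.
    """
    from .ratio_engine import series_from_faostat

    stats_nested = series_from_faostat(faostat)

    # reported 2015 totals per (adm0, GAEZ crop): 3-yr mean per FAOSTAT
    # crop, summed over the category members
    reported: dict[tuple[int, str], float] = {}
    for adm0, per_var in stats_nested.items():
        for code, series in per_var.get("H", {}).items():
            if code not in concordance.entries:
                continue
            crop = concordance.entries[code]
            m15 = three_year_mean(series, 2015)
            if m15 is None:
                continue
            reported[(adm0, crop)] = reported.get((adm0, crop), 0.0) + m15

    crops = sorted({c for c, _ in harv_layers})
    if by == "crop":
        recs = []
        for crop in crops:
            gridded = sum(
                l.masked_total() for (c, _), l in harv_layers.items() if c == crop
            )
            stat = sum(v for (_, c), v in reported.items() if c == crop)
            recs.append(_report_row({"gaez_crop": crop}, gridded, stat))
        df = pd.DataFrame(recs)
    elif by == "country":
        if fractions is None:
            raise ValueError("country report requires the cell-fraction table")
        geo = next(iter(harv_layers.values())).geo
        recs = []
        for adm0 in sorted(fractions.admin_units()):
            w = fractions.restriction_weights(adm0, geo)
            gridded = sum(float((l.values * w).sum()) for l in harv_layers.values())
            stat = sum(v for (a, _), v in reported.items() if a == adm0)
            recs.append(_report_row({"adm0_code": adm0}, gridded, stat))
        df = pd.DataFrame(recs)
    else:
        raise ValueError("by must be 'crop' or 'country'")
    return df.sort_values("gridded_1000ha", ascending=False).reset_index(drop=True)


def _report_row(head: dict, gridded: float, stat: float) -> dict:
    diff = gridded - stat
    pct = 100.0 * diff / stat if stat > 0 else np.nan
    if np.isfinite(pct) and 0 < abs(pct) < 1:
        label = f"{pct:.1g}"
    elif np.isfinite(pct):
        label = f"{pct:.0f}"
    else:
        label = ""
    return {
        **head,
        "gridded_1000ha": gridded,
        "statistic_1000ha": stat,
        "difference_1000ha": diff,
        "difference_pct": pct,
        "difference_pct_label": label,
    }
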