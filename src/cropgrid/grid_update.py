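"""Apply country change ratios to gridded 2010 layers; cap; derive yields.

A grid cell may straddle several administrative units.  The cell-fraction
table gives, for each cell k, the share f_i of its area in unit i.  The
updated harvested area in the cell is

    H_2015(k) = H_2010(k) * sum_i fhat_i * rH_i,    fhat_i = f_i / sum_j f_j

i.e. the country ratios are blended with fraction weights renormalized over
the units actually present in the cell, so a coastal cell lying wholly in
one country receives that country's ratio undiluted and the all-ratios-one
identity holds exactly.  Production updates identically with rP.

If the updated harvested areas of all crops and management systems in a
cell exceed 99% of the cell's area, all harvested areas in the cell are
scaled down proportionally to fit (the 1% headroom stands in for roads,
infrastructure and other non-crop cover).  Yield is production divided by
harvested area, zero where nothing is harvested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import CellAreaModel, Grid5Min, GridGeoreference
from .ratio_engine import ChangeRatioTable

__all__ = [
    "CellFractionTable",
    "AnnualInputs",
    "AnnualResult",
    "apply_ratios",
    "cap_annual_cell",
    "compute_yield",
    "run_annual_update",
    "MANAGEMENTS",
]

logger = logging.getLogger(__name__)

MANAGEMENTS = ("Irrigated", "Rainfed")

DEFAULT_CAP_FRACTION = 0.99


class CellFractionTable:
    """Sparse cell -> {admin unit: area fraction} mapping.

    Backed by a long DataFrame (cell_row, cell_col, adm0_code, fraction).
    Fractions are shares of the cell's *total* area in (0, 1]; their sum
    per cell may fall below 1 for coastal cells.
    """

    def __init__(self, table: pd.DataFrame):
        req = {"cell_row", "cell_col", "adm0_code", "fraction"}
        if not req <= set(table.columns):
            raise ValueError(f"fraction table needs columns {sorted(req)}")
        t = table.copy()
        t["cell_row"] = t["cell_row"].astype(int)
        t["cell_col"] = t["cell_col"].astype(int)
        t["adm0_code"] = t["adm0_code"].astype(int)
        t["fraction"] = t["fraction"].astype(float)
        if (t["fraction"] <= 0).any():
            raise ValueError("fractions must be positive")
        sums = t.groupby(["cell_row", "cell_col"])["fraction"].sum()
        if (sums > 1 + 1e-9).any():
            bad = sums[sums > 1 + 1e-9].index[0]
            raise ValueError(f"cell {bad} has fractions summing above 1")
        self.table = t.reset_index(drop=True)

    @classmethod
    def read_csv(cls, path) -> "CellFractionTable":
        return cls(pd.read_csv(path))

    def write_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def admin_units(self) -> set[int]:
        return set(self.table["adm0_code"].unique().tolist())

    def cells_of(self, adm0: int) -> pd.DataFrame:
        return self.table[self.table["adm0_code"] == adm0]

    def ratio_multiplier(
        self, ratios: ChangeRatioTable, crop: str, which: str, geo: GridGeoreference
    ) -> np.ndarray:
        """(rows, cols) multiplier grid: sum_i fhat_i * r_i; 1 elsewhere."""
        idx = 0 if which == "H" else 1
        t = self.table
        r = np.array([ratios.get(a, crop)[idx] for a in t["adm0_code"]])
        w = t["fraction"].to_numpy()
        num = pd.Series(r * w).groupby([t["cell_row"], t["cell_col"]]).sum()
        den = pd.Series(w).groupby([t["cell_row"], t["cell_col"]]).sum()
        mult = np.ones((geo.rows, geo.cols))
        rows = num.index.get_level_values(0).to_numpy()
        cols = num.index.get_level_values(1).to_numpy()
        mult[rows, cols] = num.to_numpy() / den.to_numpy()
        return mult

    def restriction_weights(
        self,
        adm0: int,
        geo: GridGeoreference,
        ratios: ChangeRatioTable | None = None,
        crop: str | None = None,
        which: str = "H",
    ) -> np.ndarray:
        """Per-cell weight attributing a layer's values to one admin unit.

        Without ratios this is fhat_i (area share).  With ratios the share
        is value-weighted, fhat_i*r_i / sum_j fhat_j*r_j, which attributes
        an updated 2015 layer consistently with how the update blended the
        ratios (the two coincide when all ratios are equal).
        """
        t = self.table
        if ratios is None:
            r = np.ones(len(t))
        else:
            idx = 0 if which == "H" else 1
            r = np.array([ratios.get(a, crop)[idx] for a in t["adm0_code"]])
        w = t["fraction"].to_numpy() * r
        den = pd.Series(w).groupby([t["cell_row"], t["cell_col"]]).sum()
        mine = t["adm0_code"].to_numpy() == adm0
        num = pd.Series(np.where(mine, w, 0.0)).groupby(
            [t["cell_row"], t["cell_col"]]
        ).sum()
        out = np.zeros((geo.rows, geo.cols))
        rows = num.index.get_level_values(0).to_numpy()
        cols = num.index.get_level_values(1).to_numpy()
        with np.errstate(invalid="ignore"):
            out[rows, cols] = np.where(
                den.to_numpy() > 0, num.to_numpy() / den.to_numpy(), 0.0
            )
        return out


def apply_ratios(
    layer2010: Grid5Min,
    fractions: CellFractionTable,
    ratios: ChangeRatioTable,
    crop: str,
    variable: str = "H",
) -> Grid5Min:
    """Update one 2010 layer to 2015 with fraction-blended country ratios.

    ``variable`` selects rH ("H") or rP ("P").  Cells without any fraction
    entry keep their 2010 value (multiplier 1); admin units absent from
    the ratio table contribute a ratio of 1.0 with a warning.  The no-data
    mask is preserved.
    """
    if variable not in ("H", "P"):
        raise ValueError("variable must be 'H' or 'P'")
    mult = fractions.ratio_multiplier(ratios, crop, variable, layer2010.geo)
    out = layer2010.copy()
    out.values = np.where(out.mask, 0.0, out.values * mult)
    return out


def cap_annual_cell(
    crop_areas: dict[str, float], cell_area: float, cap_fraction: float = DEFAULT_CAP_FRACTION
) -> dict[str, float]:
    """Scale a cell's crop areas proportionally into the 99% budget.

    Proportional scaling preserves the crop mix and cannot produce
    negative areas; cells at or under the budget pass through unchanged.
    """
    total = sum(crop_areas.values())
    budget = cap_fraction * cell_area
    if total <= budget or total == 0:
        return dict(crop_areas)
    s = budget / total
    return {k: v * s for k, v in crop_areas.items()}


def compute_yield(P: Grid5Min, H: Grid5Min) -> Grid5Min:
    """Per-cell yield in t/ha (1000 t / 1000 ha); zero where H is zero."""
    if not P.same_grid(H):
        raise ValueError("production and harvested-area grids differ")
    mask = P.mask | H.mask
    with np.errstate(divide="ignore", invalid="ignore"):
        y = np.where(H.values > 0, P.values / np.where(H.values > 0, H.values, 1.0), 0.0)
    y = np.where(mask, 0.0, y)
    return Grid5Min(y, mask, P.geo)


@dataclass
class AnnualInputs:
    """Bundle for one annual update run.

    ``harv_2010`` / ``prod_2010`` map (GAEZ crop, management) to 2010
    layers in 1000 ha / 1000 tonnes.
    """

    harv_2010: dict[tuple[str, str], Grid5Min]
    prod_2010: dict[tuple[str, str], Grid5Min]
    fractions: CellFractionTable
    ratios: ChangeRatioTable
    cap_fraction: float = DEFAULT_CAP_FRACTION

    @property
    def crops(self) -> list[str]:
        return sorted({c for c, _ in self.harv_2010})

    @property
    def geo(self) -> GridGeoreference:
        return next(iter(self.harv_2010.values())).geo


@dataclass
class AnnualResult:
    """2015 layers plus the per-country conservation report.

    ``layers`` maps (variable, crop, management) to a layer; variables are
    HarvArea, Production, Yield and managements Irrigated / Rainfed.
    ``conservation`` has one row per (adm0, crop, management) with the
    target country total (2010 total x ratio) and the achieved gridded
    total; they diverge only where the 99% cap removed area.
    """

    layers: dict[tuple[str, str, str], Grid5Min]
    conservation: pd.DataFrame
    cap_scale: np.ndarray = field(repr=False, default=None)

    def total_layer(self, variable: str, crop: str) -> Grid5Min:
        """Sum (HarvArea/Production) or combined Mean (Yield) over
        managements."""
        if variable == "Yield":
            h = self.total_layer("HarvArea", crop)
            p = self.total_layer("Production", crop)
            return compute_yield(p, h)
        a = self.layers[(variable, crop, "Irrigated")]
        b = self.layers[(variable, crop, "Rainfed")]
        out = a.copy()
        out.values = a.values + b.values
        out.mask = a.mask & b.mask
        out.values[out.mask] = 0.0
        return out


def run_annual_update(inputs: AnnualInputs) -> AnnualResult:
    """Steps of the annual 2010 -> 2015 update, in order.

    1. multiply each crop x management H and P layer by the blended
       country ratios;
    2. cap each cell whose total updated harvested area (all crops, both
       managements) exceeds ``cap_fraction`` of the cell area, scaling
       all its harvested areas proportionally (production untouched);
    3. compute yields P/H with the zero rule.

    Returns all 2015 layers and a conservation report comparing achieved
    vs target country totals.
    """
    geo = inputs.geo
    for key, layer in list(inputs.harv_2010.items()) + list(inputs.prod_2010.items()):
        if layer.geo != geo:
            raise ValueError(f"grid shape mismatch for layer {key}")

    h15: dict[tuple[str, str], Grid5Min] = {}
    p15: dict[tuple[str, str], Grid5Min] = {}
    for (crop, mgmt), layer in inputs.harv_2010.items():
        h15[(crop, mgmt)] = apply_ratios(layer, inputs.fractions, inputs.ratios, crop, "H")
    for (crop, mgmt), layer in inputs.prod_2010.items():
        p15[(crop, mgmt)] = apply_ratios(layer, inputs.fractions, inputs.ratios, crop, "P")

    # 99% cap on the all-crop harvested-area total, vectorized per cell
    areas = CellAreaModel(geo).as_grid()
    total_h = np.zeros((geo.rows, geo.cols))
    for layer in h15.values():
        total_h += layer.values
    budget = inputs.cap_fraction * areas
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = np.where(total_h > budget, budget / np.where(total_h > 0, total_h, 1.0), 1.0)
    n_capped = int((scale < 1).sum())
    if n_capped:
        logger.info("annual cap triggered in %d cells", n_capped)
    for layer in h15.values():
        layer.values *= scale

    layers: dict[tuple[str, str, str], Grid5Min] = {}
    for (crop, mgmt), layer in h15.items():
        layers[("HarvArea", crop, mgmt)] = layer
    for (crop, mgmt), layer in p15.items():
        layers[("Production", crop, mgmt)] = layer
    for (crop, mgmt) in h15:
        layers[("Yield", crop, mgmt)] = compute_yield(p15[(crop, mgmt)], h15[(crop, mgmt)])

    conservation = _conservation_report(inputs, h15)
    return AnnualResult(layers=layers, conservation=conservation, cap_scale=scale)


def _conservation_report(
    inputs: AnnualInputs, h15: dict[tuple[str, str], Grid5Min]
) -> pd.DataFrame:
    """Per-(country, crop, management) achieved vs target 2015 totals.

    2015 cell values are attributed to countries with value-consistent
    weights (fraction x ratio, renormalized) so the comparison isolates
    genuine losses (the cap) from split-cell bookkeeping.
    """
    geo = inputs.geo
    recs = []
    for adm0 in sorted(inputs.fractions.admin_units()):
        w2010 = inputs.fractions.restriction_weights(adm0, geo)
        for (crop, mgmt), l2010 in inputs.harv_2010.items():
            rh, _ = inputs.ratios.get(adm0, crop)
            target = float((l2010.values * w2010).sum()) * rh
            w2015 = inputs.fractions.restriction_weights(
                adm0, geo, inputs.ratios, crop, "H"
            )
            achieved = float((h15[(crop, mgmt)].values * w2015).sum())
            recs.append(
                {
                    "adm0_code": adm0,
                    "gaez_crop": crop,
                    "management": mgmt,
                    "target_1000ha": target,
                    "achieved_1000ha": achieved,
                    "rel_error": (achieved - target) / target if target > 0 else 0.0,
                }
            )
    return pd.DataFrame(recs)
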