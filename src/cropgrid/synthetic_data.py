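"""Miniature synthetic worlds with known ground truth.

The generator builds every input the pipeline consumes — 2010 harvested
area and production grids, FAOSTAT-style country statistics, a cell ->
country fraction table, livestock series and subcrop calendars — on a
small global-like grid, such that the statistics are *exactly* consistent
with the grids.  Each country's reported 2009-2011 values equal its
gridded 2010 totals and its 2014-2016 values equal those totals times a
chosen per-crop multiplier, so the change ratios the pipeline should
recover are known by construction and, absent capping, the updated
country totals are predictable to rounding error.

Structural features of the real inputs are reproduced on demand: border
cells split between two countries, coastal cells whose fractions sum
below one, a no-data island and a disputed territory (drawn from the
packaged special-region registry, hence pinned to "no change"), a country
that splits into two successor states mid-period ("Sudan-like"), wrapped
(Nov-Feb) growing seasons, multiple subcrops per crop, and a cell
engineered to overflow the 99% area cap.  Geography is schematic —
rectangular countries on a 36 x 72 grid of 5-degree cells — because only
the statistical structure matters to the code paths; the cells run
through exactly the same machinery as 5-arcminute ones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .concordance import (
    CropConcordance,
    MircaMatch,
    load_crop_concordance,
    load_mirca_matches,
)
from .grids import CellAreaModel, Grid5Min, GridGeoreference
from .grid_update import CellFractionTable
from .monthly_disagg import SubcropCalendar
from .ratio_engine import (
    ChangeRatioTable,
    SpecialRegionRegistry,
    load_special_regions,
)

__all__ = ["WorldConfig", "GroundTruth", "WorldBundle", "generate_world", "recovery_check"]

# registry codes reused for the synthetic island / disputed territory
ISLAND_ADM0 = 98  # Greenland's ADM0 code, in the no-data list
DISPUTED_ADM0 = 102  # Abyei's ADM0 code, in the disputed list
SPLIT_PARENT_ADM0 = 900
SPLIT_CHILD_ADM0 = (901, 902)


@dataclass(frozen=True)
class WorldConfig:
    """Parameters of a synthetic world.

    Defaults give a three-country world with three crops, both
    managements, split border cells and one coastal column; the include
    flags switch the special-case structures on.  ``multipliers`` fixes
    the true per-country per-crop (rH*, rP*); left None they are drawn
    uniformly from [0.7, 1.4].
    """

    seed: int = 42
    rows: int = 36
    cols: int = 72
    cellsize: float = 5.0
    n_countries: int = 3
    crops: tuple[str, ...] = ("Wheat", "Rice", "Maize")
    managements: tuple[str, ...] = ("Irrigated", "Rainfed")
    multipliers: dict | None = None
    sudan_split: bool = False
    no_data_island: bool = False
    disputed_area: bool = False
    wrap_season: bool = False
    multi_subcrop: bool = False
    cap_stress: bool = False
    missing_year_rate: float = 0.15
    calendar_coverage: float = 0.8
    cell_occupancy: float = 0.6
    mean_cell_area_1000ha: float = 40.0

    def geo(self) -> GridGeoreference:
        return GridGeoreference(
            rows=self.rows, cols=self.cols, west=-180.0, north=90.0, cellsize=self.cellsize
        )


@dataclass
class GroundTruth:
    """Everything a recovery test needs, derived without the pipeline."""

    expected_ratios: dict  # (adm0, crop) -> (rH*, rP*)
    expected_h2015: dict  # (adm0, crop, mgmt) -> 1000 ha
    expected_p2015: dict  # (adm0, crop, mgmt) -> 1000 t
    donor_map: dict  # (crop, mgmt, row, col) -> (donor_row, donor_col)

    def ratio_table(self, crops: tuple[str, ...]) -> ChangeRatioTable:
        t = ChangeRatioTable(crops=crops)
        for (adm0, crop), (rh, rp) in self.expected_ratios.items():
            t.set(adm0, crop, rh, rp)
        return t


@dataclass
class WorldBundle:
    """A complete input set plus its ground truth."""

    config: WorldConfig
    geo: GridGeoreference
    harv_2010: dict  # (crop, mgmt) -> Grid5Min
    prod_2010: dict
    faostat: pd.DataFrame
    fractions: CellFractionTable
    calendar: SubcropCalendar
    concordance: CropConcordance
    matches: dict[str, MircaMatch]
    registry: SpecialRegionRegistry
    split_map: dict = field(default_factory=dict)
    truth: GroundTruth | None = None


def _country_blocks(cfg: WorldConfig) -> dict[int, tuple[int, int, int, int]]:
    """adm0 -> (row0, row1, col0, col1) inclusive rectangles."""
    width = 10
    needed = cfg.n_countries * width + 10
    if needed > cfg.cols:
        raise ValueError(
            f"{cfg.n_countries} countries need {needed} columns, grid has {cfg.cols}"
        )
    blocks: dict[int, tuple[int, int, int, int]] = {}
    r0, r1 = cfg.rows // 3, 2 * cfg.rows // 3
    codes: list[int] = []
    n_plain = cfg.n_countries - (2 if cfg.sudan_split else 0)
    if n_plain < 1:
        raise ValueError("sudan_split needs n_countries >= 3")
    codes.extend(301 + j for j in range(n_plain))
    if cfg.sudan_split:
        codes.extend(SPLIT_CHILD_ADM0)
    for j, code in enumerate(codes):
        c0 = 10 + j * width
        blocks[code] = (r0, r1, c0, c0 + width - 1)
    return blocks


def generate_world(config: WorldConfig) -> WorldBundle:
    """Build the full input bundle and its ground truth.

    The same seed always produces an identical bundle (all randomness
    flows from one generator consumed in a fixed order).
    """
    rng = np.random.default_rng(config.seed)
    geo = config.geo()
    concordance = load_crop_concordance()
    matches = load_mirca_matches()
    registry = load_special_regions()
    for crop in config.crops:
        if crop not in matches:
            raise ValueError(f"unknown GAEZ crop in config: {crop}")

    blocks = _country_blocks(config)
    countries = sorted(blocks)

    # --- cell fractions: block interiors 1.0, shared borders split,
    # westmost column of the first country coastal (sum < 1)
    frac_rows: list[dict] = []
    for code in countries:
        r0, r1, c0, c1 = blocks[code]
        for r in range(r0, r1 + 1):
            for c in range(c0, c1 + 1):
                frac_rows.append(
                    {"cell_row": r, "cell_col": c, "adm0_code": code, "fraction": 1.0}
                )
    frame = pd.DataFrame(frac_rows)
    # split each border column between the neighbours 0.6 / 0.4
    for left, right in zip(countries, countries[1:]):
        _, _, _, lc1 = blocks[left]
        r0, r1, rc0, _ = blocks[right]
        if rc0 - lc1 == 1:
            border = frame["cell_col"] == rc0
            mine = border & (frame["adm0_code"] == right)
            frame.loc[mine, "fraction"] = 0.4
            extra = frame.loc[mine].copy()
            extra["adm0_code"] = left
            extra["fraction"] = 0.6
            frame = pd.concat([frame, extra], ignore_index=True)
    first = countries[0]
    coast = (frame["adm0_code"] == first) & (frame["cell_col"] == blocks[first][2])
    frame.loc[coast, "fraction"] = 0.7
    if config.no_data_island:
        frame = pd.concat(
            [frame, pd.DataFrame([{"cell_row": 5, "cell_col": 5, "adm0_code": ISLAND_ADM0, "fraction": 1.0}])],
            ignore_index=True,
        )
    if config.disputed_area:
        frame = pd.concat(
            [frame, pd.DataFrame([{"cell_row": 6, "cell_col": 60, "adm0_code": DISPUTED_ADM0, "fraction": 1.0}])],
            ignore_index=True,
        )
    fractions = CellFractionTable(frame)

    land_mask = np.ones((geo.rows, geo.cols), bool)  # True = no-data (ocean)
    land_mask[
        fractions.table["cell_row"].to_numpy(), fractions.table["cell_col"].to_numpy()
    ] = False

    # --- true multipliers
    mult: dict[tuple[int, str], tuple[float, float]] = {}
    stat_countries = [c for c in countries if c not in registry]
    for adm0 in stat_countries:
        for crop in config.crops:
            if config.multipliers and (adm0, crop) in config.multipliers:
                m = config.multipliers[(adm0, crop)]
                mult[(adm0, crop)] = (float(m[0]), float(m[1]))
            else:
                mult[(adm0, crop)] = (
                    float(rng.uniform(0.7, 1.4)),
                    float(rng.uniform(0.7, 1.4)),
                )

    # --- 2010 grids: log-normal areas over a random subset of each
    # country's cells; production = area x per-(country, crop) yield
    harv = {
        (crop, mgmt): Grid5Min(np.zeros((geo.rows, geo.cols)), land_mask.copy(), geo)
        for crop in config.crops
        for mgmt in config.managements
    }
    prod = {k: Grid5Min(np.zeros((geo.rows, geo.cols)), land_mask.copy(), geo) for k in harv}
    yields: dict[tuple[int, str], float] = {}
    all_blocks = dict(blocks)
    if config.no_data_island:
        all_blocks[ISLAND_ADM0] = (5, 5, 5, 5)
    if config.disputed_area:
        all_blocks[DISPUTED_ADM0] = (6, 6, 60, 60)
    for adm0 in sorted(all_blocks):
        r0, r1, c0, c1 = all_blocks[adm0]
        for crop in config.crops:
            yields[(adm0, crop)] = float(rng.uniform(1.0, 8.0))
            for mgmt in config.managements:
                cells = [
                    (r, c)
                    for r in range(r0, r1 + 1)
                    for c in range(c0, c1 + 1)
                    if rng.random() < config.cell_occupancy
                ]
                if not cells:
                    cells = [(r0, c0)]
                areas = rng.lognormal(
                    mean=np.log(config.mean_cell_area_1000ha), sigma=0.5, size=len(cells)
                )
                for (r, c), a in zip(cells, areas):
                    harv[(crop, mgmt)].values[r, c] += a
                    prod[(crop, mgmt)].values[r, c] += a * yields[(adm0, crop)]

    if config.cap_stress:
        # overfill one interior cell of the first country so the updated
        # total exceeds the 99% budget even at the smallest multiplier (0.7)
        r0, r1, c0, c1 = blocks[countries[0]]
        r, c = (r0 + r1) // 2, (c0 + c1) // 2
        cell_budget = CellAreaModel(geo).area_of(r)
        per_layer = 1.6 * cell_budget / max(1, len(harv))
        for (crop, mgmt), layer in harv.items():
            layer.values[r, c] = per_layer
            prod[(crop, mgmt)].values[r, c] = per_layer * yields[(countries[0], crop)]

    # --- country totals restricted through the fraction table
    h_tot: dict[tuple[int, str, str], float] = {}
    p_tot: dict[tuple[int, str, str], float] = {}
    for adm0 in sorted(all_blocks):
        w = fractions.restriction_weights(adm0, geo)
        for (crop, mgmt), layer in harv.items():
            h_tot[(adm0, crop, mgmt)] = float((layer.values * w).sum())
            p_tot[(adm0, crop, mgmt)] = float((prod[(crop, mgmt)].values * w).sum())

    # --- FAOSTAT-style statistics table
    faostat = _build_faostat(config, rng, concordance, stat_countries, h_tot, p_tot, mult)

    # --- calendars
    calendar, donor_map = _build_calendars(config, rng, geo, harv, matches)

    # --- ground truth
    expected_ratios: dict = {}
    for adm0 in sorted(all_blocks):
        for crop in config.crops:
            if adm0 in registry:
                expected_ratios[(adm0, crop)] = (1.0, 1.0)
            else:
                expected_ratios[(adm0, crop)] = mult[(adm0, crop)]
    expected_h2015 = {
        (adm0, crop, mgmt): tot * expected_ratios[(adm0, crop)][0]
        for (adm0, crop, mgmt), tot in h_tot.items()
    }
    expected_p2015 = {
        (adm0, crop, mgmt): tot * expected_ratios[(adm0, crop)][1]
        for (adm0, crop, mgmt), tot in p_tot.items()
    }
    truth = GroundTruth(
        expected_ratios=expected_ratios,
        expected_h2015=expected_h2015,
        expected_p2015=expected_p2015,
        donor_map=donor_map,
    )
    split_map = {SPLIT_PARENT_ADM0: SPLIT_CHILD_ADM0} if config.sudan_split else {}
    return WorldBundle(
        config=config,
        geo=geo,
        harv_2010=harv,
        prod_2010=prod,
        faostat=faostat,
        fractions=fractions,
        calendar=calendar,
        concordance=concordance,
        matches=matches,
        registry=registry,
        split_map=split_map,
        truth=truth,
    )


def _window_values(rng, total: float, years: tuple[int, ...], missing_rate: float):
    """Constant-valued reporting window with some years dropped (never all)."""
    keep = [y for y in years if rng.random() >= missing_rate]
    if not keep:
        keep = [years[1]]
    return {y: total for y in keep}


def _build_faostat(
    config, rng, concordance, stat_countries, h_tot, p_tot, mult
) -> pd.DataFrame:
    """Country statistics exactly consistent with the gridded 2010 totals.

    Categories with several FAOSTAT member crops split the total 60/40
    over the first two member codes (same true ratio, so the aggregate is
    exact regardless of weights).  A Sudan-like parent reports only
    pre-2012 years; its children report 2012 onwards.
    """
    recs: list[dict] = []
    split_children = set(SPLIT_CHILD_ADM0) if config.sudan_split else set()

    def emit(area, item, element, series):
        for y in sorted(series):
            recs.append(
                {
                    "area_code": area, "item_code": item, "element": element,
                    "year": y, "value": series[y],
                    "unit": "ha" if element == "area_harvested" else ("tonnes" if element == "production" else "head"),
                }
            )

    for adm0 in stat_countries:
        for crop in config.crops:
            members = concordance.members(crop)
            reported_members = [
                m for m in members if m not in concordance.no_longer_reported
            ]
            rh, rp = mult[(adm0, crop)]
            h10 = sum(h_tot[(adm0, crop, mg)] for mg in config.managements)
            p10 = sum(p_tot[(adm0, crop, mg)] for mg in config.managements)
            if not reported_members:
                # fodder-style category: herd sizes carry the ratio
                base = float(rng.uniform(1e5, 1e6))
                emit(adm0, "cattle", "stocks", _window_values(rng, base, (2009, 2010, 2011), config.missing_year_rate))
                emit(adm0, "cattle", "stocks", _window_values(rng, base * rh, (2014, 2015, 2016), config.missing_year_rate))
                emit(adm0, "buffalo", "stocks", {2010: base * 0.1, 2015: base * 0.1 * rh})
                continue
            shares = [1.0] if len(reported_members) == 1 else [0.6, 0.4]
            codes = reported_members[: len(shares)]
            for code, share in zip(codes, shares):
                if adm0 in split_children:
                    # child reports 2012 (its own 2010-equivalent total,
                    # fixing the split shares) and the 2015 window
                    emit(adm0, code, "area_harvested", {2012: h10 * share})
                    emit(adm0, code, "production", {2012: p10 * share})
                    emit(adm0, code, "area_harvested", _window_values(rng, h10 * share * rh, (2014, 2015, 2016), config.missing_year_rate))
                    emit(adm0, code, "production", _window_values(rng, p10 * share * rp, (2014, 2015, 2016), config.missing_year_rate))
                else:
                    emit(adm0, code, "area_harvested", _window_values(rng, h10 * share, (2009, 2010, 2011), config.missing_year_rate))
                    emit(adm0, code, "production", _window_values(rng, p10 * share, (2009, 2010, 2011), config.missing_year_rate))
                    emit(adm0, code, "area_harvested", _window_values(rng, h10 * share * rh, (2014, 2015, 2016), config.missing_year_rate))
                    emit(adm0, code, "production", _window_values(rng, p10 * share * rp, (2014, 2015, 2016), config.missing_year_rate))

    if config.sudan_split:
        # parent reports the children's combined totals before the split
        for crop in config.crops:
            members = [
                m for m in concordance.members(crop)
                if m not in concordance.no_longer_reported
            ]
            if not members:
                continue
            h_parent = sum(
                sum(h_tot[(ch, crop, mg)] for mg in config.managements)
                for ch in SPLIT_CHILD_ADM0
            )
            p_parent = sum(
                sum(p_tot[(ch, crop, mg)] for mg in config.managements)
                for ch in SPLIT_CHILD_ADM0
            )
            shares = [1.0] if len(members) == 1 else [0.6, 0.4]
            for code, share in zip(members[: len(shares)], shares):
                emit(SPLIT_PARENT_ADM0, code, "area_harvested", {y: h_parent * share for y in (2009, 2010, 2011)})
                emit(SPLIT_PARENT_ADM0, code, "production", {y: p_parent * share for y in (2009, 2010, 2011)})

    df = pd.DataFrame(
        recs, columns=["area_code", "item_code", "element", "year", "value", "unit"]
    )
    return df.sort_values(["area_code", "item_code", "element", "year"]).reset_index(
        drop=True
    )


def _build_calendars(config, rng, geo, harv, matches):
    """Subcrop calendars covering most growing cells; the rest borrow.

    Returns (calendar, donor map).  The donor map is computed here by an
    exhaustive great-circle scan so recovery tests need not trust the
    pipeline's own nearest-cell search.
    """
    calendar = SubcropCalendar()
    for (crop, mgmt), layer in sorted(harv.items()):
        mirca = matches[crop].mirca_crops
        grow = [tuple(int(v) for v in x) for x in np.argwhere(layer.values > 0)]
        for idx, (r, c) in enumerate(grow):
            if idx > 0 and rng.random() >= config.calendar_coverage:
                continue  # no calendar here: pipeline must borrow a donor
            seasons = _seasons_for(config, rng, crop)
            # multi-match crops: spread entries across both MIRCA crops
            for n, (s, e) in enumerate(seasons):
                mc = mirca[n % len(mirca)]
                calendar.add(r, c, mc, mgmt, s, e, float(rng.lognormal(np.log(5.0), 0.4)))

    # donor map by exhaustive scan over the cells that actually carry the
    # pooled MIRCA calendar (different GAEZ crops may share a MIRCA class,
    # so a skipped cell can still have inherited a calendar)
    donor_map: dict = {}
    for (crop, mgmt), layer in sorted(harv.items()):
        grow = [tuple(int(v) for v in x) for x in np.argwhere(layer.values > 0)]
        occ = {
            tuple(int(v) for v in x)
            for x in calendar.occupied_cells(matches[crop].mirca_crops, mgmt)
        }
        unc = [cell for cell in grow if cell not in occ]
        if not unc:
            continue
        occ_sorted = sorted(occ)
        lat = np.deg2rad(np.array([geo.lat_center(r) for r, _ in occ_sorted]))
        lon = np.deg2rad(np.array([geo.lon_center(c) for _, c in occ_sorted]))
        for r, c in unc:
            la, lo = np.deg2rad(geo.lat_center(r)), np.deg2rad(geo.lon_center(c))
            a = np.sin((lat - la) / 2) ** 2 + np.cos(la) * np.cos(lat) * np.sin((lon - lo) / 2) ** 2
            d = 2 * np.arcsin(np.minimum(1.0, np.sqrt(a)))
            best = min(
                range(len(occ_sorted)),
                key=lambda i: (round(float(d[i]), 12), occ_sorted[i]),
            )
            donor_map[(crop, mgmt, r, c)] = occ_sorted[best]
    return calendar, donor_map


def _seasons_for(config, rng, crop) -> list[tuple[int, int]]:
    if config.multi_subcrop and crop == "Rice":
        return [(2, 5), (7, 10)]  # two disjoint seasons -> bimodal series
    if config.multi_subcrop and rng.random() < 0.5:
        n = int(rng.integers(2, 4))
        seasons = [(1, 3), (5, 7), (9, 11)][:n]
    else:
        seasons = [(4, 9)]
    if config.wrap_season and rng.random() < 0.3:
        seasons[-1] = (11, 2)
    return seasons


def recovery_check(
    result,
    truth: GroundTruth,
    fractions: CellFractionTable,
    crops: tuple[str, ...],
    tolerance: float = 1e-6,
) -> pd.DataFrame:
    """Compare achieved 2015 country totals against the ground truth.

    Attributes each updated cell to countries with the truth's own
    ratio-consistent weights (independent of the pipeline's bookkeeping)
    and reports relative errors; rows exceeding ``tolerance`` are
    flagged.  In a world where no cell hits the cap all flags are False.
    """
    ratios = truth.ratio_table(crops)
    geo = next(iter(result.layers.values())).geo
    recs = []
    admins = sorted({a for a, _ in truth.expected_ratios})
    for adm0 in admins:
        for (variable, expected) in (
            ("HarvArea", truth.expected_h2015),
            ("Production", truth.expected_p2015),
        ):
            which = "H" if variable == "HarvArea" else "P"
            for crop in crops:
                w = fractions.restriction_weights(adm0, geo, ratios, crop, which)
                for mgmt in ("Irrigated", "Rainfed"):
                    key = (variable, crop, mgmt)
                    if key not in result.layers:
                        continue
                    achieved = float((result.layers[key].values * w).sum())
                    exp = expected.get((adm0, crop, mgmt), 0.0)
                    rel = (achieved - exp) / exp if exp > 0 else 0.0
                    recs.append(
                        {
                            "adm0_code": adm0, "gaez_crop": crop,
                            "management": mgmt, "variable": variable,
                            "expected": exp, "achieved": achieved,
                            "rel_error": rel, "exceeds_tol": abs(rel) > tolerance,
                        }
                    )
    return pd.DataFrame(recs)


# ---------------------------------------------------------------------------
# bundle <-> disk, in the same external formats the pipeline reads


def save_bundle(bundle: WorldBundle, out_dir) -> None:
    """Write the bundle in the pipeline's external formats.

    Layout: ``grids2010/GAEZAct2010_{Var}_{Crop}_{Mgmt}.tif``,
    ``faostat.csv``, ``cell_fractions.csv``, ``calendars.csv`` and a
    ``world.json`` with the georeference, split map and ground truth.
    """
    from .geo_io import compose_filename, write_raster

    out = Path(out_dir)
    (out / "grids2010").mkdir(parents=True, exist_ok=True)
    for (crop, mgmt), layer in sorted(bundle.harv_2010.items()):
        write_raster(layer, out / "grids2010" / compose_filename("HarvArea", crop, mgmt, year_tag="2010"))
    for (crop, mgmt), layer in sorted(bundle.prod_2010.items()):
        write_raster(layer, out / "grids2010" / compose_filename("Production", crop, mgmt, year_tag="2010"))
    bundle.faostat.to_csv(out / "faostat.csv", index=False)
    bundle.fractions.write_csv(out / "cell_fractions.csv")
    bundle.calendar.write_csv(out / "calendars.csv")
    meta = {
        "rows": bundle.geo.rows,
        "cols": bundle.geo.cols,
        "west": bundle.geo.west,
        "north": bundle.geo.north,
        "cellsize": bundle.geo.cellsize,
        "crops": list(bundle.config.crops),
        "managements": list(bundle.config.managements),
        "split_map": {str(k): list(v) for k, v in bundle.split_map.items()},
        "truth": {
            "expected_ratios": [
                [a, c, rh, rp] for (a, c), (rh, rp) in sorted(bundle.truth.expected_ratios.items())
            ],
            "expected_h2015": [
                [a, c, m, v] for (a, c, m), v in sorted(bundle.truth.expected_h2015.items())
            ],
            "expected_p2015": [
                [a, c, m, v] for (a, c, m), v in sorted(bundle.truth.expected_p2015.items())
            ],
            "donor_map": [
                [cr, mg, r, c, dr, dc]
                for (cr, mg, r, c), (dr, dc) in sorted(bundle.truth.donor_map.items())
            ],
        }
        if bundle.truth
        else None,
    }
    (out / "world.json").write_text(json.dumps(meta, indent=1, sort_keys=True))


def load_bundle(bundle_dir) -> WorldBundle:
    """Read a bundle previously written by :func:`save_bundle`."""
    from .geo_io import compose_filename, read_raster

    src = Path(bundle_dir)
    meta = json.loads((src / "world.json").read_text())
    geo = GridGeoreference(
        rows=meta["rows"], cols=meta["cols"], west=meta["west"],
        north=meta["north"], cellsize=meta["cellsize"],
    )
    crops = tuple(meta["crops"])
    mgmts = tuple(meta["managements"])
    harv = {}
    prod = {}
    for crop in crops:
        for mgmt in mgmts:
            harv[(crop, mgmt)] = read_raster(
                src / "grids2010" / compose_filename("HarvArea", crop, mgmt, year_tag="2010")
            )
            prod[(crop, mgmt)] = read_raster(
                src / "grids2010" / compose_filename("Production", crop, mgmt, year_tag="2010")
            )
    truth = None
    if meta.get("truth"):
        t = meta["truth"]
        truth = GroundTruth(
            expected_ratios={(a, c): (rh, rp) for a, c, rh, rp in t["expected_ratios"]},
            expected_h2015={(a, c, m): v for a, c, m, v in t["expected_h2015"]},
            expected_p2015={(a, c, m): v for a, c, m, v in t["expected_p2015"]},
            donor_map={(cr, mg, r, c): (dr, dc) for cr, mg, r, c, dr, dc in t["donor_map"]},
        )
    cfg = WorldConfig(rows=meta["rows"], cols=meta["cols"], cellsize=meta["cellsize"], crops=crops, managements=mgmts)
    return WorldBundle(
        config=cfg,
        geo=geo,
        harv_2010=harv,
        prod_2010=prod,
        faostat=pd.read_csv(src / "faostat.csv"),
        fractions=CellFractionTable.read_csv(src / "cell_fractions.csv"),
        calendar=SubcropCalendar.read_csv(src / "calendars.csv"),
        concordance=load_crop_concordance(),
        matches=load_mirca_matches(),
        registry=load_special_regions(),
        split_map={int(k): tuple(v) for k, v in meta.get("split_map", {}).items()},
        truth=truth,
    )
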