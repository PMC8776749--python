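"""Country-level 2010->2015 change ratios per GAEZ crop.

For every country and FAOSTAT crop the engine forms three-year means of
harvested area H and production P around 2010 (2009-2011) and 2015
(2014-2016), takes the ratio rH = H_2015/H_2010 (and rP likewise), and
aggregates the FAOSTAT-crop ratios to the 26 GAEZ categories by a
2015-harvested-area-weighted average.  Zero or unreported statistics yield
a ratio of 1.0 (no change).  Fodder crops, no longer reported by FAOSTAT,
take their ratio from the change in national cattle+buffalo herd size.
Countries in the special-region registry (small islands with no reported
data, and disputed territories) are pinned to 1.0 for every crop.
A country that split during the period ("Sudan-like") can have its
pre-split statistics apportioned to the successor states by their shares
in the first jointly-reported year.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from .concordance import CropConcordance, canonical_gaez_name

__all__ = [
    "SpecialRegionRegistry",
    "ChangeRatioTable",
    "three_year_mean",
    "compute_change_ratio",
    "aggregate_to_gaez",
    "fodder_ratio",
    "split_parent_country",
    "build_ratio_table",
    "load_special_regions",
    "read_faostat_csv",
    "series_from_faostat",
    "livestock_from_faostat",
]

logger = logging.getLogger(__name__)

MISSING = None  # sentinel for an unreported statistic

WINDOW_2010 = (2009, 2010, 2011)
WINDOW_2015 = (2014, 2015, 2016)


@dataclass(frozen=True)
class SpecialRegionRegistry:
    """Administrative units whose ratios are pinned to 1.0.

    ``no_data_regions``: small regions and islands with no FAOSTAT crop
    statistics at all.  ``disputed_regions``: territories assigned to a
    dispute rather than a country in the cell-fraction table.
    """

    no_data_regions: frozenset[int]
    disputed_regions: frozenset[int]

    def __post_init__(self) -> None:
        if self.no_data_regions & self.disputed_regions:
            raise ValueError("a region cannot be both no-data and disputed")

    @property
    def all_regions(self) -> frozenset[int]:
        return self.no_data_regions | self.disputed_regions

    def __contains__(self, adm0: int) -> bool:
        return adm0 in self.all_regions


def load_special_regions(path=None) -> SpecialRegionRegistry:
    """Load the registry CSV (packaged canonical list by default).

    The canonical file carries the 49 no-data regions and 9 disputed areas
    keyed by GAUL ADM0 code.
    """
    src = path if path is not None else resources.files("cropgrid.data").joinpath(
        "special_regions.csv"
    )
    df = pd.read_csv(src)
    nd = frozenset(int(c) for c in df.loc[df["kind"] == "no_data", "adm0_code"])
    da = frozenset(int(c) for c in df.loc[df["kind"] == "disputed", "adm0_code"])
    return SpecialRegionRegistry(no_data_regions=nd, disputed_regions=da)


@dataclass
class ChangeRatioTable:
    """(adm0 code, GAEZ crop) -> (rH, rP); defaults to (1, 1) when asked
    for an unknown country (with a warning, once per country)."""

    ratios: dict[tuple[int, str], tuple[float, float]] = field(default_factory=dict)
    crops: tuple[str, ...] = ()
    _warned: set[int] = field(default_factory=set, repr=False)

    def set(self, adm0: int, crop: str, rh: float, rp: float) -> None:
        if rh <= 0 or rp <= 0:
            raise ValueError(f"ratios must be positive, got rH={rh}, rP={rp}")
        self.ratios[(adm0, canonical_gaez_name(crop))] = (float(rh), float(rp))

    def get(self, adm0: int, crop: str) -> tuple[float, float]:
        key = (adm0, canonical_gaez_name(crop))
        if key not in self.ratios:
            if adm0 not in self._warned:
                logger.warning(
                    "no change ratio for admin unit %s; assuming no change", adm0
                )
                self._warned.add(adm0)
            return (1.0, 1.0)
        return self.ratios[key]

    def countries(self) -> set[int]:
        return {adm0 for adm0, _ in self.ratios}

    def to_frame(self) -> pd.DataFrame:
        recs = [
            {"adm0_code": a, "gaez_crop": c, "rH": rh, "rP": rp}
            for (a, c), (rh, rp) in sorted(self.ratios.items())
        ]
        return pd.DataFrame(recs, columns=["adm0_code", "gaez_crop", "rH", "rP"])


def three_year_mean(series: dict[int, float | None], center_year: int) -> float | None:
    """Mean of the values present in the window center_year +/- 1.

    Years missing from the mapping (or mapped to None/NaN) are dropped; if
    the whole window is absent the result is None.  Averaging smooths
    single-year outliers and tolerates reporting gaps.
    """
    vals = []
    for y in (center_year - 1, center_year, center_year + 1):
        v = series.get(y)
        if v is None:
            continue
        v = float(v)
        if math.isnan(v):
            continue
        vals.append(v)
    if not vals:
        return None
    if all(v == vals[0] for v in vals):
        return vals[0]  # exact: keeps flat series ulp-clean through division
    return sum(vals) / len(vals)


def compute_change_ratio(v2010: float | None, v2015: float | None) -> float:
    """v2015 / v2010, with the no-information rule.

    Zero or unreported values on either side give 1.0 (no change assumed).
    Negative statistics are invalid.
    """
    for v in (v2010, v2015):
        if v is not None and v < 0:
            raise ValueError(f"negative statistic: {v}")
    if v2010 is None or v2015 is None or v2010 == 0 or v2015 == 0:
        return 1.0
    return float(v2015) / float(v2010)


def aggregate_to_gaez(
    faostat_ratios: dict[int, float],
    weights_2015: dict[int, float],
    members: list[int],
) -> float:
    """Area-weighted mean ratio over the member FAOSTAT crops.

    Weights are 2015 harvested areas; members with missing or zero weight
    drop out.  If no member carries weight the aggregate defaults to 1.0.
    """
    if not members:
        raise ValueError("members must be nonempty")
    num = den = 0.0
    for c in members:
        w = weights_2015.get(c) or 0.0
        if w > 0:
            num += faostat_ratios.get(c, 1.0) * w
            den += w
    return num / den if den > 0 else 1.0


def fodder_ratio(livestock: dict[str, dict[int, float | None]]) -> float:
    """Change ratio for fodder crops from national herd sizes.

    Cattle and buffalo head counts are summed per year, three-year means
    taken around 2010 and 2015, and their ratio returned under the same
    zero/missing rule as crops.
    """
    yearly: dict[int, float] = {}
    for _species, series in livestock.items():
        for y, v in series.items():
            if v is None or (isinstance(v, float) and math.isnan(v)):
                continue
            yearly[y] = yearly.get(y, 0.0) + float(v)
    return compute_change_ratio(
        three_year_mean(yearly, 2010), three_year_mean(yearly, 2015)
    )


def split_parent_country(
    parent_2010: dict[int, float],
    children_2012: dict[int, dict[int, float]],
) -> dict[int, dict[int, float]]:
    """Apportion a pre-split country's statistics to its successors.

    Each crop's parent value is split by the children's shares in the
    first year both successors reported (2012 for the Sudan case).  If
    neither child reports the crop the value splits evenly.
    """
    children = sorted(children_2012)
    out: dict[int, dict[int, float]] = {ch: {} for ch in children}
    for crop, parent_val in parent_2010.items():
        if parent_val < 0 or any(
            children_2012[ch].get(crop, 0.0) < 0 for ch in children
        ):
            raise ValueError("negative statistic in split")
        total = sum(children_2012[ch].get(crop, 0.0) for ch in children)
        for ch in children:
            share = (
                children_2012[ch].get(crop, 0.0) / total
                if total > 0
                else 1.0 / len(children)
            )
            out[ch][crop] = parent_val * share
    return out


def _crop_ratios_for_country(
    h_series: dict[int, dict[int, float | None]],
    p_series: dict[int, dict[int, float | None]],
) -> tuple[dict[int, float], dict[int, float], dict[int, float]]:
    """Per-FAOSTAT-crop (rH, rP, weight=3yr-mean 2015 harvested area)."""
    rh: dict[int, float] = {}
    rp: dict[int, float] = {}
    w15: dict[int, float] = {}
    for code in set(h_series) | set(p_series):
        h = h_series.get(code, {})
        p = p_series.get(code, {})
        h10, h15 = three_year_mean(h, 2010), three_year_mean(h, 2015)
        p10, p15 = three_year_mean(p, 2010), three_year_mean(p, 2015)
        rh[code] = compute_change_ratio(h10, h15)
        rp[code] = compute_change_ratio(p10, p15)
        w15[code] = h15 or 0.0
    return rh, rp, w15


def build_ratio_table(
    stats: "pd.DataFrame | dict",
    livestock: "pd.DataFrame | dict",
    concordance: CropConcordance,
    registry: SpecialRegionRegistry | None = None,
    countries: set[int] | None = None,
    split_map: dict[int, tuple[int, int]] | None = None,
    split_year: int = 2012,
) -> ChangeRatioTable:
    """Assemble the full (country, GAEZ crop) -> (rH, rP) table.

    Parameters
    ----------
    stats
        FAOSTAT-style long table (see :func:`read_faostat_csv`) or nested
        dict ``{adm0: {"H": {code: {year: v}}, "P": {...}}}``.
    livestock
        Long table with element ``stocks`` or dict
        ``{adm0: {species: {year: head}}}``.
    concordance
        FAOSTAT->GAEZ mapping; its fodder flag selects the livestock rule.
    registry
        Regions pinned to (1, 1) for every crop.
    countries
        Admin units that must appear in the output even without any
        statistics (they get all-1.0 entries with a warning).
    split_map
        ``{parent_adm0: (child_a, child_b)}`` Sudan-like splits: parent
        rows before ``split_year`` are apportioned to the children by
        their ``split_year`` shares before ratios are computed.

    Every listed country receives exactly one (rH, rP) pair per GAEZ
    category in the concordance.
    """
    if isinstance(stats, pd.DataFrame):
        stats = series_from_faostat(stats)
    if isinstance(livestock, pd.DataFrame):
        livestock = livestock_from_faostat(livestock)
    stats = {int(k): v for k, v in stats.items()}
    livestock = {int(k): v for k, v in livestock.items()}

    if split_map:
        stats = _apply_splits(stats, split_map, split_year)

    gaez_crops = tuple(
        sorted(concordance.gaez_categories)
    )
    fodder_codes = concordance.no_longer_reported
    table = ChangeRatioTable(crops=gaez_crops)

    all_countries = set(stats) | set(livestock)
    if countries:
        all_countries |= {int(c) for c in countries}
    if registry:
        all_countries |= set(registry.all_regions)

    for adm0 in sorted(all_countries):
        if registry is not None and adm0 in registry:
            for crop in gaez_crops:
                table.set(adm0, crop, 1.0, 1.0)
            continue
        cstats = stats.get(adm0, {"H": {}, "P": {}})
        if adm0 not in stats and adm0 not in livestock:
            logger.warning(
                "admin unit %s has no statistics; all ratios set to 1.0", adm0
            )
        rh_c, rp_c, w15 = _crop_ratios_for_country(
            cstats.get("H", {}), cstats.get("P", {})
        )
        for crop in gaez_crops:
            all_members = concordance.members(crop)
            reported = [c for c in all_members if c not in fodder_codes]
            if all_members and not reported:
                # fodder: no crop statistics exist, use herd-size change
                r = fodder_ratio(livestock.get(adm0, {}))
                table.set(adm0, crop, r, r)
            elif not all_members:
                table.set(adm0, crop, 1.0, 1.0)
            else:
                rh = aggregate_to_gaez(rh_c, w15, reported)
                rp = aggregate_to_gaez(rp_c, w15, reported)
                table.set(adm0, crop, rh, rp)
    return table


def _apply_splits(
    stats: dict,
    split_map: dict[int, tuple[int, int]],
    split_year: int,
) -> dict:
    """Replace parent-country rows with virtual successor-state rows."""
    out = dict(stats)
    for parent, children in split_map.items():
        if parent not in out:
            continue
        pstats = out.pop(parent)
        for var in ("H", "P"):
            pser = pstats.get(var, {})
            parent_pre = {
                code: {y: v for y, v in ser.items() if y < split_year}
                for code, ser in pser.items()
            }
            # per-crop split-year child shares
            child_ref = {
                ch: {
                    code: (out.get(ch, {}).get(var, {}).get(code, {}) or {}).get(
                        split_year, 0.0
                    )
                    or 0.0
                    for code in pser
                }
                for ch in children
            }
            for code, ser in parent_pre.items():
                for y, v in ser.items():
                    if v is None:
                        continue
                    total = sum(child_ref[ch].get(code, 0.0) for ch in children)
                    for ch in children:
                        share = (
                            child_ref[ch][code] / total
                            if total > 0
                            else 1.0 / len(children)
                        )
                        out.setdefault(ch, {}).setdefault(var, {}).setdefault(
                            code, {}
                        )[y] = v * share
    return out


# ---------------------------------------------------------------------------
# FAOSTAT-style CSV adapters

_ELEMENTS = {"area_harvested": "H", "production": "P"}


def read_faostat_csv(path) -> pd.DataFrame:
    """Read a FAOSTAT production-domain-style CSV.

    Expected columns: area_code, item_code, element, year, value, unit.
    Rows with missing values are tolerated (treated as unreported).
    """
    df = pd.read_csv(path)
    required = {"area_code", "item_code", "element", "year", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"FAOSTAT table missing columns: {sorted(missing)}")
    return df


def series_from_faostat(df: pd.DataFrame) -> dict:
    """Pivot a long FAOSTAT table to {adm0: {"H"/"P": {code: {year: v}}}}."""
    out: dict = {}
    sub = df[df["element"].isin(_ELEMENTS)]
    for rec in sub.itertuples(index=False):
        v = rec.value
        if v is None or (isinstance(v, float) and math.isnan(v)):
            continue
        var = _ELEMENTS[rec.element]
        out.setdefault(int(rec.area_code), {}).setdefault(var, {}).setdefault(
            int(rec.item_code), {}
        )[int(rec.year)] = float(v)
    return out


def livestock_from_faostat(df: pd.DataFrame) -> dict:
    """Pivot livestock 'stocks' rows to {adm0: {species: {year: head}}}.

    The item_code column may carry species names or codes; both work since
    the fodder rule sums across species anyway.
    """
    out: dict = {}
    sub = df[df["element"] == "stocks"]
    for rec in sub.itertuples(index=False):
        v = rec.value
        if v is None or (isinstance(v, float) and math.isnan(v)):
            continue
        out.setdefault(int(rec.area_code), {}).setdefault(str(rec.item_code), {})[
            int(rec.year)
        ] = float(v)
    return out
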