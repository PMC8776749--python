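"""Crop harmonization tables.

Two concordances drive the pipeline:

* FAOSTAT -> GAEZ: maps each FAOSTAT production-domain crop code to one of
  the 26 GAEZ crop categories.  Fodder crops are flagged: FAOSTAT stopped
  reporting their harvested area, so their change ratio comes from
  livestock herd sizes instead.
* GAEZ -> MIRCA2000: maps each GAEZ category to one or two MIRCA2000 crop
  classes (whose calendars carry the monthly disaggregation) and assigns a
  removal order, the priority used when monthly cropland overflows a grid
  cell (1 = removed first; staples carry large numbers so their area
  survives truncation).

Both tables ship as plain-text CSV package data so synthetic worlds can run
with reduced crop sets; the packaged files reproduce the canonical tables.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

__all__ = [
    "GAEZ_CROPS",
    "CropConcordance",
    "MircaMatch",
    "normalize_crop_name",
    "load_crop_concordance",
    "load_mirca_matches",
    "lookup_gaez_category",
    "lookup_mirca_match",
    "validate_concordance",
    "UnmappedCropError",
]

#: The 26 GAEZ crop category names, canonical spellings.
GAEZ_CROPS: tuple[str, ...] = (
    "Wheat", "Rice", "Maize", "Sorghum", "Millet", "Barley", "Other_cereals",
    "Potato_&_Sweet_potato", "Cassava", "Yams_and_other_roots", "Sugarbeet",
    "Sugarcane", "Pulses", "Soybean", "Rapeseed", "Sunflower", "Groundnut",
    "Oil_palm_fruit", "Olives", "Cotton", "Tobacco", "Banana", "Stimulants",
    "Vegetables", "Crops_NES", "Fodder_crop",
)

# Spellings of the same category differ across published tables
# ("Foddercrops" vs "Fodder_crop"); resolved after normalization.
_ALIASES = {
    "foddercrops": "fodder_crop",
    "fodder_crops": "fodder_crop",
    "cropsnes": "crops_nes",
}


class UnmappedCropError(KeyError):
    """Raised for a crop code or name absent from the concordance."""


def normalize_crop_name(name: str) -> str:
    """Canonical comparison key for a crop name.

    Lowercase, '&' read as 'and', runs of non-alphanumerics collapsed to a
    single underscore.  Needed because source tables mix spellings such as
    "Potato_&_Sweet_potato" and "Potato & Sweet potato".
    """
    s = name.strip().lower().replace("&", " and ")
    s = re.sub(r"[^a-z0-9]+", "_", s).strip("_")
    return _ALIASES.get(s, s)


_CANON = {normalize_crop_name(c): c for c in GAEZ_CROPS}


def canonical_gaez_name(name: str) -> str:
    """Map any accepted spelling to the canonical GAEZ category name."""
    key = normalize_crop_name(name)
    if key not in _CANON:
        raise UnmappedCropError(f"unknown GAEZ crop: {name!r}")
    return _CANON[key]


@dataclass
class CropConcordance:
    """FAOSTAT crop code -> GAEZ category, with fodder flags."""

    entries: dict[int, str]
    no_longer_reported: set[int] = field(default_factory=set)
    names: dict[int, str] = field(default_factory=dict)

    @property
    def gaez_categories(self) -> set[str]:
        return set(self.entries.values())

    def members(self, gaez_crop: str) -> list[int]:
        """FAOSTAT codes aggregated into one GAEZ category."""
        g = canonical_gaez_name(gaez_crop)
        return sorted(c for c, v in self.entries.items() if v == g)


@dataclass(frozen=True)
class MircaMatch:
    """GAEZ category matched to 1-2 MIRCA2000 crops plus removal order."""

    gaez_crop: str
    mirca_crops: tuple[str, ...]
    one_to_one: bool
    removal_order: int


def _data_path(filename: str):
    return resources.files("cropgrid.data").joinpath(filename)


def load_crop_concordance(path=None) -> CropConcordance:
    """Read a FAOSTAT->GAEZ concordance CSV (packaged canonical by default).

    Columns: faostat_code, faostat_name, gaez_crop, no_longer_reported.
    """
    src = path if path is not None else _data_path("crop_concordance.csv")
    df = pd.read_csv(src)
    entries: dict[int, str] = {}
    flags: set[int] = set()
    names: dict[int, str] = {}
    for rec in df.itertuples(index=False):
        code = int(rec.faostat_code)
        if code in entries:
            raise ValueError(f"duplicate FAOSTAT code {code} in concordance")
        entries[code] = canonical_gaez_name(rec.gaez_crop)
        names[code] = str(rec.faostat_name)
        if getattr(rec, "no_longer_reported", 0):
            flags.add(code)
    return CropConcordance(entries=entries, no_longer_reported=flags, names=names)


def load_mirca_matches(path=None) -> dict[str, MircaMatch]:
    """Read the GAEZ->MIRCA match table (packaged canonical by default).

    Columns: gaez_crop, mirca_crops (';'-separated), one_to_one,
    removal_order.
    """
    src = path if path is not None else _data_path("mirca_matches.csv")
    df = pd.read_csv(src)
    out: dict[str, MircaMatch] = {}
    for rec in df.itertuples(index=False):
        g = canonical_gaez_name(rec.gaez_crop)
        out[g] = MircaMatch(
            gaez_crop=g,
            mirca_crops=tuple(str(rec.mirca_crops).split(";")),
            one_to_one=bool(int(rec.one_to_one)),
            removal_order=int(rec.removal_order),
        )
    return out


def lookup_gaez_category(concordance: CropConcordance, faostat_code: int) -> str:
    """GAEZ category for a FAOSTAT production-domain crop code."""
    try:
        return concordance.entries[int(faostat_code)]
    except KeyError:
        raise UnmappedCropError(f"unmapped crop code: {faostat_code}") from None


def lookup_mirca_match(matches: dict[str, MircaMatch], gaez_crop: str) -> MircaMatch:
    """MIRCA match entry for a GAEZ category (any accepted spelling)."""
    g = canonical_gaez_name(gaez_crop)
    try:
        return matches[g]
    except KeyError:
        raise UnmappedCropError(f"unknown GAEZ crop: {gaez_crop}") from None


def validate_concordance(
    concordance: CropConcordance,
    matches: dict[str, MircaMatch] | list[MircaMatch] | None = None,
    expected_categories: tuple[str, ...] = GAEZ_CROPS,
) -> list[str]:
    """Report structural problems; an empty list means well-formed tables.

    Checks: every expected GAEZ category present in the concordance and in
    the match table; no stray categories; removal orders within 1..21;
    every match carries at least one MIRCA crop.
    """
    problems: list[str] = []
    expected = {canonical_gaez_name(c) for c in expected_categories}
    if isinstance(concordance, pd.DataFrame):
        dupes = concordance.loc[
            concordance["faostat_code"].duplicated(), "faostat_code"
        ]
        for code in sorted(set(int(c) for c in dupes)):
            problems.append(f"duplicate FAOSTAT code: {code}")
        present = {canonical_gaez_name(g) for g in concordance["gaez_crop"]}
    else:
        present = concordance.gaez_categories
    for missing in sorted(expected - present):
        problems.append(f"missing GAEZ category in concordance: {missing}")
    for stray in sorted(present - expected):
        problems.append(f"unexpected GAEZ category in concordance: {stray}")
    if matches is not None:
        if isinstance(matches, dict):
            match_list = list(matches.values())
        else:
            match_list = list(matches)
        seen: set[str] = set()
        for m in match_list:
            if m.gaez_crop in seen:
                problems.append(f"duplicate match entry: {m.gaez_crop}")
            seen.add(m.gaez_crop)
            if not 1 <= m.removal_order <= 21:
                problems.append(
                    f"removal order out of range for {m.gaez_crop}: {m.removal_order}"
                )
            if not m.mirca_crops:
                problems.append(f"no MIRCA crop for {m.gaez_crop}")
        for missing in sorted(expected - seen):
            problems.append(f"missing GAEZ category in match table: {missing}")
    return problems
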