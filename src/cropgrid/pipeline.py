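"""End-to-end orchestration: bundle in, updated layers and reports out.

Thin glue over the library modules so the same entry points back both the
command-line interface and scripted use: build the ratio table from the
statistics, update the grids, disaggregate to months, and run the
validation reports.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .grid_update import AnnualInputs, AnnualResult, run_annual_update
from .monthly_disagg import MonthlyResult, run_monthly
from .ratio_engine import ChangeRatioTable, build_ratio_table
from .synthetic_data import WorldBundle
from .zonal_validation import ZoneMap, compare_tables, harvested_area_report, zonal_sum

__all__ = [
    "ratio_table_for_bundle",
    "run_annual_pipeline",
    "run_monthly_pipeline",
    "validation_reports",
]


def ratio_table_for_bundle(bundle: WorldBundle) -> ChangeRatioTable:
    """Country change ratios from the bundle's statistics tables."""
    return build_ratio_table(
        bundle.faostat,
        bundle.faostat,
        bundle.concordance,
        registry=bundle.registry,
        countries=bundle.fractions.admin_units(),
        split_map=bundle.split_map or None,
    )


def run_annual_pipeline(
    bundle: WorldBundle,
    out_dir=None,
    cap_fraction: float = 0.99,
) -> tuple[AnnualResult, list[str]]:
    """Update the bundle's 2010 grids to 2015; optionally write GeoTIFFs.

    Returns the result and the list of file names written (empty when
    ``out_dir`` is None).
    """
    ratios = ratio_table_for_bundle(bundle)
    inputs = AnnualInputs(
        harv_2010=bundle.harv_2010,
        prod_2010=bundle.prod_2010,
        fractions=bundle.fractions,
        ratios=ratios,
        cap_fraction=cap_fraction,
    )
    result = run_annual_update(inputs)
    written: list[str] = []
    if out_dir is not None:
        from .geo_io import write_annual_result

        written = write_annual_result(result, out_dir)
        result.conservation.to_csv(Path(out_dir) / "conservation_report.csv", index=False)
    return result, written


def run_monthly_pipeline(
    bundle: WorldBundle,
    annual: AnnualResult,
    out_dir=None,
    cap_fraction: float = 0.99,
) -> tuple[MonthlyResult, list[str]]:
    """Disaggregate updated annual harvested area into monthly cubes."""
    annual_harv = {
        (crop, mgmt): layer
        for (var, crop, mgmt), layer in annual.layers.items()
        if var == "HarvArea"
    }
    result = run_monthly(annual_harv, bundle.calendar, bundle.matches, cap_fraction)
    written: list[str] = []
    if out_dir is not None:
        from .geo_io import write_monthly_result

        written = write_monthly_result(result, out_dir)
        pd.DataFrame(
            {"month": range(1, 13), "removed_1000ha": result.removed_by_month}
        ).to_csv(Path(out_dir) / "removal_report.csv", index=False)
    return result, written


def validation_reports(
    bundle: WorldBundle,
    annual: AnnualResult,
    out_dir=None,
) -> dict[str, pd.DataFrame]:
    """Harvested-area comparisons by crop and country, plus a zonal OLS
    self-check of the gridded totals against the statistics."""
    harv_layers = {
        (crop, mgmt): layer
        for (var, crop, mgmt), layer in annual.layers.items()
        if var == "HarvArea"
    }
    by_crop = harvested_area_report(harv_layers, bundle.faostat, bundle.concordance, by="crop")
    by_country = harvested_area_report(
        harv_layers, bundle.faostat, bundle.concordance,
        by="country", fractions=bundle.fractions,
    )
    zones = ZoneMap.from_fractions(bundle.fractions, bundle.geo)
    gridded: dict[int, float] = {}
    for layer in harv_layers.values():
        totals, _ = zonal_sum(layer, zones)
        for z, v in totals.items():
            gridded[z] = gridded.get(z, 0.0) + v
    stat = dict(
        zip(by_country["adm0_code"].astype(int), by_country["statistic_1000ha"])
    )
    reg = None
    try:
        reg = compare_tables(gridded, stat)
    except ValueError:
        pass  # too few zones to regress
    reports = {"by_crop": by_crop, "by_country": by_country}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        by_crop.to_csv(out / "harvested_area_by_crop.csv", index=False)
        by_country.to_csv(out / "harvested_area_by_country.csv", index=False)
        if reg is not None:
            pd.DataFrame([reg.__dict__]).to_csv(out / "zonal_regression.csv", index=False)
    if reg is not None:
        reports["zonal_regression"] = pd.DataFrame([reg.__dict__])
    return reports
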