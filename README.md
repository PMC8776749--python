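# cropgrid

Updating gridded global crop data with country-level statistics, and
disaggregating annual harvested area into monthly physical cropland area.

## The problem

Global hydrology, land-surface and food-system models need gridded inputs of
crop harvested area, production and yield, split by crop and by irrigated vs
rainfed management — and often at monthly resolution, because what matters
for water and energy fluxes is the land a crop actually occupies each month.
Gridded crop products (GAEZ-style 5-arcminute maps, MIRCA2000 monthly
growing-area grids) are rebuilt only rarely, while national statistics
(FAOSTAT) are updated every year. `cropgrid` implements the bridge: it
carries an existing circa-2010 gridded baseline forward to circa 2015 using
only country-level statistic changes, then converts the updated annual
harvested areas into monthly physical areas using MIRCA2000-style crop
calendars with up to five "subcrops" per crop.

## The method

For each country *c* and crop, change ratios are formed from three-year
averaged national statistics,

    rH_c = H_2015 / H_2010        rP_c = P_2015 / P_2010

with the 2010 and 2015 values taken as 2009–2011 and 2014–2016 means; zero
or unreported statistics give a ratio of 1 (no change). Ratios of the ~160
FAOSTAT crops are aggregated to 26 GAEZ crop categories by a 2015
harvested-area-weighted mean. Fodder crops, no longer reported by FAOSTAT,
take the ratio of national cattle+buffalo herd sizes. Each grid cell *k* is
updated through the cell→country fraction table *f\_i^k* (GAUL-style):

    H_2015(k) = H_2010(k) · Σ_i  f̂_i^k · rH_{c,i},     f̂ = f / Σf

If a cell's total updated harvested area exceeds 99% of the cell area, all
its crop areas are scaled down proportionally (1% is reserved for roads and
other infrastructure). Yield is Y = P/H, zero where H = 0.

Monthly disaggregation assigns each crop's annual harvested area H_G to the
matched MIRCA2000 crop's subcrops in proportion to their calendar areas,
A_G = Σ_n (A_{M,n}/H_M)·H_G, borrowing the nearest cell's calendar where a
growing cell has none. A per-month 99% cap removes excess area crop by crop
in a removal-order priority (rainfed before irrigated, staples last).

Special cases handled: a country that split mid-period (Sudan-like; the
pre-split statistics are apportioned to the successors), 49 small no-data
regions and 9 disputed territories pinned to "no change".

## Worked example

```
$ python examples/02_annual_update.py
updated layers: 18 (3 variables x 3 crops x 2 managements)
max |relative error| of country totals vs ground truth: 1.88e-16
example: country 301 Wheat Irrigated expected 5023.4, achieved 5023.4 (1000 ha)
18 GeoTIFFs written, e.g. GAEZAct2015_HarvArea_Maize_Irrigated.tif
```

The synthetic world's statistics are exactly consistent with its 2010 grids,
so the updated country totals must equal (2010 total) × (true ratio); the
reported error is at machine precision. `examples/03_monthly_disaggregation.py`
prints the global monthly rice series of a two-season calendar world — two
plateaus (Feb–May and Jul–Oct) whose areas each sum with the other to the
annual harvested area — and `examples/01_change_ratios.py` and
`examples/04_validation.py` demonstrate ratio assembly and the validation
reports.

A thin CLI wraps the same pipeline:

```
cropgrid synth  --seed 5 --out bundle/ --all-flags
cropgrid annual --bundle bundle/ --out annual/
cropgrid monthly --bundle bundle/ --out monthly/
cropgrid validate --bundle bundle/ --out reports/
```

Outputs follow the published conventions:
`GAEZAct2015_{HarvArea|Production|Yield}_{Crop}_{Irrigated|Rainfed|Total|Mean}.tif`
(float32 GeoTIFF, WGS84 lon/lat, no-data −3.4e+38) and
`GAEZ_CropArea_{Crop}_{subcrop}_{Irrigated|Rainfed}.nc` (12-layer
compressed NetCDF-4, 1000 ha per cell).

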