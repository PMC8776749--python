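# Methods

This note records the model, the numerical choices, and what the synthetic
worlds do and do not establish.

## Change ratios (ratio_engine)

National harvested area H and production P per FAOSTAT crop are averaged
over 2009–2011 and 2014–2016 and the ratios rH = H₂₀₁₅/H₂₀₁₀,
rP = P₂₀₁₅/P₂₀₁₀ formed per country. Choices:

- **Missing years.** A three-year window uses the mean of whatever years are
  present; the window is "missing" only when all three are. This is the
  point of averaging (robustness to reporting gaps and outliers).
  A mean over identical values returns the value itself rather than
  `sum/len`; this keeps a flat series exactly flat in floating point, so
  the no-change identity below is bit-exact even when the two windows
  retain different numbers of years.
- **Zero/missing rule.** If either window is zero or missing the ratio is
  1.0 — no information means no change. Negative statistics are rejected.
- **Aggregation to the 26 GAEZ categories.** Multi-crop categories take the
  harvested-area-weighted mean of member ratios, weights being the 2015
  (2014–2016 mean) harvested areas. Both rH and rP use *area* weights. If
  no member carries weight the aggregate is 1.0.
- **Fodder.** FAOSTAT stopped reporting fodder-crop areas; the fodder ratio
  is the change in summed national cattle+buffalo head counts (head counts
  summed across species *before* the ratio, not species-wise averaged),
  under the same windows and zero/missing rule. One of the canonical
  fodder rows has no FAOSTAT code ("Forage & Silage crops"); the packaged
  concordance lists only coded crops.
- **Country splits.** For a Sudan-like split, pre-split statistics are
  apportioned to the successor states by their per-crop shares in the
  first jointly-reported year (2012); if neither successor reports a crop
  the split is 50/50. Ratios are then computed per successor as usual.
- **Special regions.** The packaged registry pins 49 no-data regions and 9
  disputed territories (by GAUL ADM0 code) to ratio 1.0 for every crop.
- A country present in the cell-fraction table but absent from statistics
  and registry receives all-1.0 ratios with a logged warning.

## Grid update (grid_update)

Cells are updated as H₂₀₁₅(k) = H₂₀₁₀(k)·Σᵢ f̂ᵢᵏ·rHᵢ with fraction weights
renormalized over the admin units present in the cell (f̂ = f/Σf). The
unnormalized form would scale a coastal cell lying 70% in one country by
0.7·r, conflating land fraction with ratio weighting and breaking the
identity that all-unit ratios leave the grid unchanged; renormalization is
the package's design choice where the printed convention is ambiguous.

The 99% cap compares the sum of *all* crop harvested areas (both
managements) in a cell against 0.99 of the full spherical cell area and
scales all areas proportionally. Proportional scaling preserves the crop
mix and cannot go negative (an equal absolute subtraction could).
Production is not capped — the cap models a land constraint, not an output
constraint — so capped cells show correspondingly higher yields.

Cell areas come from the authalic sphere (R = 6 371 007.2 m):
A = R²·Δλ·(sin φ_N − sin φ_S), exact for lon/lat rectangles on the sphere,
symmetric about the equator and monotone toward the poles. At 5 arcmin the
equatorial cell is ≈ 8.586 × 1000 ha.

Yield is P/H with Y = 0 wherever H = 0 (including P > 0, H = 0, which
cannot arise from the update itself). The "Total" management layers are
sums of irrigated + rainfed; the "Mean" yield layer is total production
over total harvested area.

Country-total bookkeeping: when reporting achieved totals, a split cell's
updated value is attributed to its countries by fraction-times-ratio
weights (renormalized). This is the attribution implied by the update
formula itself; with it, the conservation law "country 2015 total =
country 2010 total × ratio" holds exactly wherever the cap did not bite.

## Monthly disaggregation (monthly_disagg)

For each crop×management with any updated area: the matched MIRCA2000
crop's subcrop calendar in the cell (up to 5 subcrops, each a start month,
end month and physical area A_{M,n}, constant over its season; seasons may
wrap December) is rescaled so subcrop n carries (A_{M,n}/H_M)·H_G in each
growing month, H_M = Σ A_{M,n}. A single subcrop therefore carries exactly
H_G. Choices:

- **Multi-match crops** (two MIRCA classes): the subcrop lists are pooled
  and H_M is their combined area, preserving both seasonal patterns. A
  pooled list longer than five subcrops is rejected.
- **Donor cells.** A growing cell with no calendar borrows the
  great-circle-nearest cell (cell-center haversine) holding the matched
  calendar *within the same management*; ties break to the lowest
  (row, col). Distances are rounded at 1e-12 rad before comparison so that
  geometrically symmetric candidates tie exactly.
- **Monthly cap.** Applied independently per month: if a cell-month's
  total over all crops and managements exceeds 0.99 of cell area, area is
  removed crop by crop — every rainfed crop in ascending removal order
  (ties alphabetical by crop name), then every irrigated crop — zeroing
  each in turn, the last crop touched reduced partially. Removal operates
  at crop level; all of a reduced crop's subcrops are scaled by the same
  post-removal fraction. Per-month independence can break a subcrop's
  constancy across its season; this is accepted as the faithful reading of
  a per-month check. Note that after the *annual* cap, monthly totals
  cannot exceed the budget (monthly physical area is bounded by annual
  harvested area), so monthly removal only acts when the annual cap is
  relaxed or inputs come from elsewhere; the machinery is exercised and
  reported regardless.
- **Empty layers** (e.g. irrigated cassava, all-zero by construction in
  the baseline) produce no monthly product.
- The removal report gives the maximum monthly removed area and its share
  of the pre-truncation peak monthly global cropland.

## File conventions (geo_io)

Annual layers: float32 GeoTIFF, WGS84 lon/lat north-up, uncompressed
striped layout, no-data −3.39999999999999996e+38, named
`GAEZAct2015_{Variable}_{Crop}_{Management}.tif`. Monthly cubes: NetCDF-4,
zlib level 7, 12-month variable in 1000 ha, fill value −3.4e+38, named
`GAEZ_CropArea_{Crop}_{subcrop}_{Management}.nc`. Values are double
precision in memory and narrowed to float32 only on write; round-trips are
bit-exact for float32-representable values. The GeoTIFF georeferencing is
written directly as the standard tags (ModelPixelScale, ModelTiepoint,
GeoKeyDirectory → EPSG:4326, GDAL_NODATA).

## Validation (zonal_validation)

Zonal sums are exact per-zone totals with unzoned mass reported separately
(conservation: zones + unzoned = global). Product comparisons use OLS
*with* intercept — regression lines of gridded products against references
generally do not pass through the origin — reporting r², slope and RMSE of
residuals; slope < 1 means the first product under-reports the second.
Cropland extent bounds per cell: minimum = the largest monthly total
(maximal multi-cropping re-use of land), maximum = min(annual harvested
area, cell area) (no re-use); the minimum is additionally clipped to the
maximum. Percent differences below 1% are labelled to one significant
figure in the harvested-area reports.

## Synthetic worlds (synthetic_data)

Default miniature: a 36 × 72 grid of 5° cells (same code paths as 5-arcmin
grids, seconds-scale tests), three to four rectangular countries of ~130
cells each with log-normal per-cell areas (median 40 × 1000 ha per layer,
far from the cap), 60/40 split border cells, one coastal column with
fraction 0.7, true multipliers drawn U(0.7, 1.4) per country×crop unless
pinned. Statistics are generated *from* the gridded totals, so ratio
recovery is exact by construction; reporting noise is realized as missing
years (never an entire window), not value jitter, to exercise the
three-year-mean rule. Optional structures: Sudan-like split (parent 900 →
children 901/902), a no-data island and a disputed cell using registry
codes, wrapped seasons, multi-subcrop calendars (rice gets Feb–May +
Jul–Oct), and a cap-stress cell overfilled to 1.6× its area so the 99% cap
must fire at any multiplier. Calendars cover ~80% of growing cells; the
rest exercise donor borrowing, with the expected donor recorded in the
ground truth by an exhaustive scan.

What passing tests show: the bookkeeping laws (conservation, identity,
caps, monthly/annual consistency, yield identity) hold on inputs with the
pipeline's full structural variety. What they do not show: fidelity of any
real-world geography or statistics — the generator makes no attempt to
mimic actual crop distributions, and results on real archives inherit
whatever biases those carry.

## Problem sizes

Tests and the acceptance script run the full pipeline on the 36 × 72
worlds (26 crops × 2 managements for the inventory check; 1 000 random
cell-months for the truncation oracle), completing in seconds. The
canonical 2160 × 4320 global grid uses identical code paths; the grid
update is vectorized per layer, while the monthly step iterates over
growing cells and is the part that would dominate at global scale.

## Known limitations

- Crop calendars are frozen at their MIRCA2000-style inputs; no calendar
  or rotation change over the update period is represented.
- The update cannot move a crop into cells where the baseline had none;
  a crop reported in 2015 but absent from the 2010 grids stays absent
  (the ratio applies only where 2010 area > 0).
- Irrigated/rainfed proportions are inherited from the baseline grids;
  no re-partitioning is attempted.
- Whether the 99% caps should compare against land area rather than full
  cell area in coastal cells is ambiguous in the conventions this package
  follows; full spherical cell area is used.
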