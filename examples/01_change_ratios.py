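"""Country change ratios from reported statistics.

Builds a tiny two-country statistics table for wheat, where country 301
doubled its harvested area between the 2009-2011 and 2014-2016 windows
and country 302 halved it, then assembles the full ratio table.
"""

import pandas as pd

from cropgrid import build_ratio_table, load_crop_concordance, load_special_regions

records = []
for adm0, mult in ((301, 2.0), (302, 0.5)):
    for year in (2009, 2010, 2011):
        records.append((adm0, 15, "area_harvested", year, 100.0))
        records.append((adm0, 15, "production", year, 250.0))
    for year in (2014, 2015, 2016):
        records.append((adm0, 15, "area_harvested", year, 100.0 * mult))
        records.append((adm0, 15, "production", year, 250.0 * mult))
stats = pd.DataFrame(
    records, columns=["area_code", "item_code", "element", "year", "value"]
)

table = build_ratio_table(
    stats, stats, load_crop_concordance(), registry=load_special_regions()
)

for adm0 in (301, 302):
    rh, rp = table.get(adm0, "Wheat")
    print(f"country {adm0}: rH = {rh:.2f}, rP = {rp:.2f}")
rh, rp = table.get(301, "Rice")
print(f"country 301 rice (unreported): rH = {rh:.2f}, rP = {rp:.2f}")
rh, _ = table.get(98, "Wheat")
print(f"registry island (Greenland, 98): rH = {rh:.2f}")

# rH/rP are 2015/2010 ratios of 3-year-averaged national statistics:
# 2.00 and 0.50 recover the constructed changes; unreported crops and
# registry regions default to 1.00 (no change).
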