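"""Recompute change statistics from the published Palawan area record.

Applies the package's percent-change arithmetic to the bundled table of
published regional mangrove areas (Palawan, Puerto Princesa City, Taytay,
Aborlan, 1988-2020) and to the projected 2030/2050 areas, writing the
result table under results/.
"""

import pandas as pd

from analysis_common import RESULTS
from tidemark.published import load_published_areas, published_change

PERIODS = [(1988, 1998), (1998, 2008), (2013, 2020)]

areas = load_published_areas()
rows = []
for region in ("Palawan", "PPC", "Taytay", "Aborlan"):
    for y1, y2 in PERIODS:
        have = set(areas[(areas.region == region)
                         & (areas["class"] == "mangrove")
                         & (areas.kind == "observed")].year)
        if {y1, y2} <= have:
            rec = published_change(region, y1, y2)
            rows.append({"region": region, "period": f"{y1}-{y2}",
                         "area_initial_ha": rec.S_i, "area_final_ha": rec.S_j,
                         "delta_ha": round(rec.delta, 1),
                         "percent": round(rec.percent, 2),
                         "direction": rec.direction})

for cls, year in (("mangrove", 2030), ("mangrove", 2050),
                  ("non_mangrove", 2030), ("non_mangrove", 2050)):
    rec = published_change("Palawan", 2020, year, cls=cls, kind_j="projected")
    rows.append({"region": "Palawan", "period": f"2020-{year} (projected)",
                 "area_initial_ha": rec.S_i, "area_final_ha": rec.S_j,
                 "delta_ha": round(rec.delta, 1),
                 "percent": round(rec.percent, 2),
                 "direction": rec.direction})

df = pd.DataFrame(rows)
RESULTS.mkdir(exist_ok=True)
df.to_csv(RESULTS / "published_changes.csv", index=False)
print(df.to_string(index=False))
print(f"\nwrote {RESULTS / 'published_changes.csv'}")
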