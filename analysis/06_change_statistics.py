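"""Area series, percent change and transition matrices between epochs.

From the classified maps: per-class areas (0.09 ha/pixel), the signed
percent change (S_j - S_i)/S_i x 100 for each consecutive period, and the
row-stochastic Markov transition matrix per interval.
"""

import pandas as pd

from analysis_common import export_table, run_config
from tidemark.pipeline import run_pipeline

cfg = run_config()
run_pipeline(cfg, ("change",))

export_table(cfg.out / "change" / "areas.csv")
changes = pd.read_csv(export_table(cfg.out / "change" / "changes.csv"))
mangrove = changes[changes["class"] == 1]
print("mangrove change per period:")
print(mangrove[["from", "to", "area_initial_ha", "area_final_ha",
                "delta_ha", "percent", "direction"]].to_string(index=False))

first = sorted(cfg.out.glob("change/transition_*.csv"))[0]
print(f"\nfirst-interval transition matrix ({first.name}):")
print(pd.read_csv(first, index_col=0).to_string())
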