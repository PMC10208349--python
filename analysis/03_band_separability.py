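"""Rank bands by Jeffries-Matusita separability and select the classifier
inputs.

Pools mangrove / non-mangrove reflectance samples across all epochs, scores
each band's J-M distance in [0, 2], drops bands below 1.0 and keeps the top
three.  The designed SWIR1 contrast (dark mangrove canopies) should win.
"""

import pandas as pd

from analysis_common import export_table, run_config
from tidemark.pipeline import run_pipeline

cfg = run_config()
run_pipeline(cfg, ("separability",))

df = pd.read_csv(export_table(cfg.out / "separability" / "jm.csv"))
print(df.sort_values("jm", ascending=False).to_string(index=False))
print("selected:", ", ".join(df[df.selected == 1]
                             .sort_values("jm", ascending=False).band))
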