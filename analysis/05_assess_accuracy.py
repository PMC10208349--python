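"""Score each classified map against the true landscape.

Writes per-epoch confusion matrices (rows = reference, columns =
predicted) plus overall accuracy, producer's/user's accuracy and Cohen's
kappa.
"""

import pandas as pd

from analysis_common import export_table, run_config
from tidemark.pipeline import run_pipeline

cfg = run_config()
run_pipeline(cfg, ("assess",))

df = pd.read_csv(export_table(cfg.out / "assessment" / "metrics.csv"))
print(df.to_string(index=False))
print(f"mean overall accuracy: {df.overall.mean():.4f}; "
      f"mean kappa: {df.kappa.mean():.4f}")
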