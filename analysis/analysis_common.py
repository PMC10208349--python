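"""Shared run configuration for the numbered analysis drivers.

All drivers operate on one pipeline output tree under ``scratch/pipeline``
(rasters and intermediates) with the benchmark landscape: 256x256 pixels
at 30 m (~5900 ha), five epochs 1988-2008 on a 5-year step, generating
matrix [[0.9, 0.1], [0.2, 0.8]], seed 42.  Summary tables are copied to
``results/``.  Run the drivers in order (01 → 08); each is re-runnable.
"""

import shutil
from pathlib import Path

from tidemark.pipeline import PipelineConfig

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"


def run_config(seed: int = 42) -> PipelineConfig:
    return PipelineConfig(
        out=SCRATCH / "pipeline", seed=seed,
        landscape=dict(n_rows=256, n_cols=256, n_epochs=5, seed=seed),
        horizons_years=(10.0, 30.0))


def export_table(src: Path) -> Path:
    """Copy a stage's CSV into results/ for the record."""
    RESULTS.mkdir(exist_ok=True)
    dst = RESULTS / src.name
    shutil.copyfile(src, dst)
    return dst
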