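"""Calibrate the DN scenes to DOS1-corrected TOA reflectance.

Applies the radiometric chain per epoch and band: DN → at-sensor radiance
(linear gain/bias from the MTL metadata), dark-object path-radiance
subtraction, then top-of-atmosphere reflectance.  Cloud-masked cells become
nodata and stay excluded downstream.
"""

import numpy as np

from analysis_common import run_config
from tidemark.pipeline import run_pipeline
from tidemark.raster import read_raster
from tidemark.synthetic import load_fixture_manifest

cfg = run_config()
run_pipeline(cfg, ("calibrate",))

manifest = load_fixture_manifest(cfg.out / "fixture")
year = manifest["epochs"][0]
print(f"reflectance scenes under {cfg.out / 'reflectance'}")
for band in ("SWIR1", "NIR", "Red"):
    r = read_raster(cfg.out / "reflectance" / str(year) / f"{band}.tif")
    vals = r.valid_values()
    print(f"  {year} {band}: reflectance {vals.min():.3f}-{vals.max():.3f}, "
          f"mean {np.mean(vals):.3f}")
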