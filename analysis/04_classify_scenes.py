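"""Classify every epoch with the RBF-kernel SVM.

Trains on 400 random pixels per class from the first epoch (g = 0.091,
C = 100) against the true class map, then predicts a mangrove /
non-mangrove map for each epoch.  The fitted model is serialized next to
the maps.
"""

from analysis_common import run_config
from tidemark.classify import load_model
from tidemark.pipeline import run_pipeline

cfg = run_config()
run_pipeline(cfg, ("classify",))

model = load_model(cfg.out / "classified" / "model.npz")
print(f"classified maps under {cfg.out / 'classified'}")
print(f"bands: {', '.join(model.band_labels)}; "
      f"g={model.config.g}, C={model.config.C}")
print(f"training pixels per class: {model.class_counts}")
print(f"support vectors: {len(model.support_vectors)}")
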