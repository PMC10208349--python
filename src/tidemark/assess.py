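"""Confusion-matrix accuracy assessment.

Orientation is fixed and stated in every output: rows are the reference
(ground truth) class, columns the predicted class.  From the matrix come
overall accuracy, per-class producer's accuracy (1 − omission error, the
row-wise recall), per-class user's accuracy (1 − commission error, the
column-wise precision) and Cohen's kappa

    κ = (p_o − p_e) / (1 − p_e),

with observed agreement p_o = trace/total and chance agreement
p_e = Σ_i (row_i · col_i) / total².  A class with an empty row or column
yields NaN ("missing") for the affected metric rather than a silent 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .raster import CLASS_CODES, ClassRaster, RasterError

__all__ = ["ConfusionMatrix", "AccuracyMetrics", "confusion", "accuracy_metrics"]


@dataclass
class ConfusionMatrix:
    """q×q count matrix; rows = reference class, columns = predicted class."""

    counts: np.ndarray
    labels: tuple[int, ...] = CLASS_CODES

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        q = len(self.labels)
        if self.counts.shape != (q, q):
            raise ValueError("counts must be q x q for q labels")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.counts.sum() == 0:
            raise ValueError("confusion matrix is empty")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        idx = [f"ref_{c}" for c in self.labels]
        cols = [f"pred_{c}" for c in self.labels]
        return pd.DataFrame(self.counts, index=idx, columns=cols)


def confusion(reference: ClassRaster, predicted: ClassRaster,
              labels: tuple[int, ...] = CLASS_CODES) -> ConfusionMatrix:
    """Cross-tabulate two co-registered class maps.

    Cells that are nodata in either map are excluded; raises if no jointly
    classified pixel remains.
    """
    if reference.geometry != predicted.geometry:
        raise RasterError("maps must be co-registered")
    joint = reference.valid & predicted.valid
    if not joint.any():
        raise RasterError("no jointly classified pixels")
    ref = reference.codes[joint]
    pred = predicted.codes[joint]
    q = len(labels)
    pos = {c: i for i, c in enumerate(labels)}
    idx = np.vectorize(pos.get)(ref) * q + np.vectorize(pos.get)(pred)
    counts = np.bincount(idx, minlength=q * q).reshape(q, q)
    return ConfusionMatrix(counts, labels)


@dataclass
class AccuracyMetrics:
    """Map-accuracy summary; per-class entries are keyed by class code and
    may be NaN when the class is absent from reference or prediction."""

    overall: float
    kappa: float
    producers: dict[int, float] = field(default_factory=dict)
    users: dict[int, float] = field(default_factory=dict)
    omission: dict[int, float] = field(default_factory=dict)
    commission: dict[int, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"class": c,
                 "producers_accuracy": self.producers[c],
                 "users_accuracy": self.users[c],
                 "omission_error": self.omission[c],
                 "commission_error": self.commission[c]}
                for c in self.producers]
        df = pd.DataFrame(rows)
        df.attrs["overall"] = self.overall
        df.attrs["kappa"] = self.kappa
        return df


def accuracy_metrics(cm: ConfusionMatrix) -> AccuracyMetrics:
    """All standard map-accuracy statistics from one confusion matrix."""
    counts = cm.counts.astype(float)
    total = counts.sum()
    diag = np.diag(counts)
    rows = counts.sum(axis=1)
    cols = counts.sum(axis=0)

    overall = float(diag.sum() / total)
    p_e = float((rows * cols).sum() / total ** 2)
    kappa = float("nan") if p_e == 1.0 else (overall - p_e) / (1.0 - p_e)

    producers, users, omission, commission = {}, {}, {}, {}
    for i, label in enumerate(cm.labels):
        producers[label] = float(diag[i] / rows[i]) if rows[i] > 0 else float("nan")
        users[label] = float(diag[i] / cols[i]) if cols[i] > 0 else float("nan")
        omission[label] = 1.0 - producers[label]
        commission[label] = 1.0 - users[label]
    return AccuracyMetrics(overall, kappa, producers, users, omission, commission)
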