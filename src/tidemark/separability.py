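"""Jeffries–Matusita spectral separability and band selection.

The J–M distance between two class distributions on one band,

    JM = 2·(1 − e^(−B)),

uses the Bhattacharyya distance for univariate Gaussians,

    B = (1/8)·(μ₁−μ₂)²·2/(σ₁²+σ₂²) + (1/2)·ln[(σ₁²+σ₂²)/(2σ₁σ₂)].

JM lies in [0, 2]; 2 means fully separable classes, values below 1 flag
bands likely to confuse the classes.  Bands scoring below a removal
threshold are dropped and the best few survivors (by JM, descending) are
kept for classification — for mangrove work this characteristically selects
SWIR1–NIR–Red, because mangrove canopies are distinctively dark in the
short-wave infrared.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .raster import BAND_LABELS, CLASS_CODES, ClassRaster, MultiBandScene

__all__ = ["ClassSampleSet", "jm_distance", "jm_table", "select_bands",
           "samples_from_scene", "BAND_PRIORITY"]

#: Tie-break order for equal JM scores (field convention: SWIR1 first).
BAND_PRIORITY = ("SWIR1", "NIR", "Red", "SWIR2", "Green", "Blue", "Thermal")


@dataclass
class ClassSampleSet:
    """Reflectance samples per class per band, with first two moments.

    ``samples[class_code][band_label]`` is a 1-D array; moments use the
    unbiased (n−1) variance estimator.  Pooling samples from several sensors
    into one set gives the "overall" per-band distance.
    """

    samples: dict[int, dict[str, np.ndarray]] = field(default_factory=dict)

    def add(self, class_code: int, band_label: str, values) -> None:
        arr = np.asarray(values, dtype=float).ravel()
        band = self.samples.setdefault(class_code, {})
        band[band_label] = (np.concatenate([band[band_label], arr])
                            if band_label in band else arr)

    def moments(self, class_code: int, band_label: str) -> tuple[float, float]:
        """(mean, sd) with the n−1 estimator; requires ≥2 samples."""
        arr = self.samples[class_code][band_label]
        if arr.size < 2:
            raise ValueError("need at least 2 samples per class per band")
        return float(arr.mean()), float(arr.std(ddof=1))

    @property
    def bands(self) -> list[str]:
        labs = set()
        for per_band in self.samples.values():
            labs |= set(per_band)
        return [b for b in BAND_LABELS if b in labs]


def jm_distance(samples_a, samples_b) -> float:
    """Jeffries–Matusita distance between two univariate sample sets.

    Gaussian form from the sample moments; symmetric in its arguments and
    bounded in [0, 2].  Raises if either class has zero variance (the
    Bhattacharyya log term degenerates).
    """
    a = np.asarray(samples_a, dtype=float).ravel()
    b = np.asarray(samples_b, dtype=float).ravel()
    if a.size < 2 or b.size < 2:
        raise ValueError("each class needs at least 2 samples")
    m1, s1 = a.mean(), a.std(ddof=1)
    m2, s2 = b.mean(), b.std(ddof=1)
    if s1 <= 0 or s2 <= 0:
        raise ValueError("zero variance in one class; JM undefined")
    v1, v2 = s1 * s1, s2 * s2
    bhat = ((m1 - m2) ** 2 / (4.0 * (v1 + v2))
            + 0.5 * math.log((v1 + v2) / (2.0 * s1 * s2)))
    return 2.0 * (1.0 - math.exp(-bhat))


def jm_table(samples: ClassSampleSet,
             classes: tuple[int, int] = CLASS_CODES) -> dict[str, float]:
    """Per-band JM distance between the two classes, keyed by band label."""
    c1, c2 = classes
    return {b: jm_distance(samples.samples[c1][b], samples.samples[c2][b])
            for b in samples.bands}


def select_bands(table: dict[str, float], removal_threshold: float = 1.0,
                 n_keep: int = 3) -> list[str]:
    """Drop bands with JM below the removal threshold, rank survivors by JM
    descending and keep the best ``n_keep``.

    Ties break by the fixed band priority order.  If fewer than ``n_keep``
    bands survive, all survivors are returned with a warning.
    """
    if not table:
        raise ValueError("empty separability table")
    survivors = {b: v for b, v in table.items() if v >= removal_threshold}
    order = {b: i for i, b in enumerate(BAND_PRIORITY)}
    ranked = sorted(survivors, key=lambda b: (-survivors[b], order.get(b, 99)))
    if len(ranked) < n_keep:
        warnings.warn(
            f"only {len(ranked)} bands reach JM >= {removal_threshold}; "
            f"returning all of them", stacklevel=2)
        return ranked
    return ranked[:n_keep]


def samples_from_scene(scene: MultiBandScene, truth: ClassRaster,
                       band_labels=None) -> ClassSampleSet:
    """Collect per-class reflectance samples from a scene under a class map.

    Only cells valid in the band and classified (non-nodata) in the map
    contribute.
    """
    labels = band_labels if band_labels is not None else list(scene.bands)
    out = ClassSampleSet()
    for lab in labels:
        band = scene.bands[lab]
        for code in CLASS_CODES:
            sel = band.validity_mask & (truth.codes == code)
            out.add(code, lab, band.values[sel])
    return out
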