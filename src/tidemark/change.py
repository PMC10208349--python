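"""Area statistics, percent change, Markov transition estimation, multi-
horizon projection and chi-squared validation.

Change between two co-registered class maps is summarised two ways:

* **Area bookkeeping** — class pixel counts × pixel area (0.09 ha for the
  30 m grid) and the signed percent change
  ``(S_j − S_i)/S_i × 100`` between the areas of a class at two dates.

* **Markov chain** — the per-pixel cross-tabulation n_ij (class i at date 1
  → class j at date 2) normalised row-wise, p_ij = n_ij / n_i, gives a
  row-stochastic transition matrix for the interval Δt = t₂ − t₁.  Future
  class proportions follow the row-vector convention

      v_{t+h}ᵀ = v_tᵀ · Mʰ,   h = horizon / interval,

  which conserves total area exactly (each row of M sums to 1).  Integer
  powers use repeated multiplication; fractional horizons use the
  eigendecomposition-based matrix power with any small negative entries
  clipped to zero and rows renormalised — the standard annualisation repair
  in land-change modelling.

Projected-versus-observed agreement is tested with Pearson's chi-squared,
χ² = Σ (O−E)²/E on the per-class values with (q−1)² degrees of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .raster import CLASS_CODES, ClassRaster, RasterError

__all__ = [
    "AreaSummary", "ChangeRecord", "TransitionCounts", "TransitionMatrix",
    "ClassProportions", "ChiSquareResult",
    "class_areas", "percent_change", "estimate_transition",
    "project_markov", "project_series", "stationary_distribution",
    "chi_square_validate",
]

#: Hectares per pixel on the 30 m grid.
PIXEL_AREA_HA_30M = 0.09


@dataclass
class AreaSummary:
    """Per-class area for one epoch, in hectares."""

    epoch: int
    areas_ha: dict[int, float]
    pixel_area_ha: float = PIXEL_AREA_HA_30M
    pixel_counts: dict[int, int] = field(default_factory=dict)

    @property
    def total_ha(self) -> float:
        return float(sum(self.areas_ha.values()))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"epoch": self.epoch, "class": c, "area_ha": a,
              "pixels": self.pixel_counts.get(c)}
             for c, a in self.areas_ha.items()])


@dataclass(frozen=True)
class ChangeRecord:
    """Signed area change of one class between two dates.

    percent = (S_j − S_i)/S_i × 100; direction is "gain" for positive delta,
    "loss" for negative, "stable" at exactly zero.
    """

    S_i: float
    S_j: float

    @property
    def delta(self) -> float:
        return self.S_j - self.S_i

    @property
    def percent(self) -> float:
        return (self.S_j - self.S_i) / self.S_i * 100.0

    @property
    def direction(self) -> str:
        return "gain" if self.delta > 0 else ("loss" if self.delta < 0 else "stable")


@dataclass
class TransitionCounts:
    """Pixel-level change matrix: n[i, j] pixels went class i → class j."""

    n: np.ndarray
    labels: tuple[int, ...] = CLASS_CODES

    def __post_init__(self) -> None:
        self.n = np.asarray(self.n, dtype=np.int64)
        if (self.n < 0).any():
            raise ValueError("transition counts must be non-negative")

    @property
    def row_totals(self) -> np.ndarray:
        return self.n.sum(axis=1)


@dataclass
class TransitionMatrix:
    """Row-stochastic transition probabilities over one time interval."""

    p: np.ndarray
    interval_years: float
    labels: tuple[int, ...] = CLASS_CODES

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if (self.p < -1e-12).any() or (self.p > 1 + 1e-12).any():
            raise ValueError("transition probabilities must lie in [0, 1]")
        if not np.allclose(self.p.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each row must sum to 1")
        if not self.interval_years > 0:
            raise ValueError("interval_years must be positive")

    def to_frame(self) -> pd.DataFrame:
        idx = [f"from_{c}" for c in self.labels]
        cols = [f"to_{c}" for c in self.labels]
        return pd.DataFrame(self.p, index=idx, columns=cols)


@dataclass
class ClassProportions:
    """Length-q vector of class area proportions summing to 1, with the
    fixed total study area they refer to."""

    v: np.ndarray
    total_area_ha: float
    labels: tuple[int, ...] = CLASS_CODES

    def __post_init__(self) -> None:
        self.v = np.asarray(self.v, dtype=float)
        if (self.v < -1e-12).any():
            raise ValueError("proportions must be non-negative")
        if not np.isclose(self.v.sum(), 1.0, atol=1e-9):
            raise ValueError("proportions must sum to 1")

    def areas_ha(self) -> dict[int, float]:
        return {c: float(p * self.total_area_ha)
                for c, p in zip(self.labels, self.v)}

    @classmethod
    def from_areas(cls, areas: AreaSummary,
                   labels: tuple[int, ...] = CLASS_CODES) -> "ClassProportions":
        vec = np.array([areas.areas_ha.get(c, 0.0) for c in labels])
        total = vec.sum()
        if total <= 0:
            raise ValueError("total area must be positive")
        return cls(vec / total, float(total), labels)


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    critical: float
    alpha: float

    @property
    def reject(self) -> bool:
        """True when the statistic exceeds the tabled critical value."""
        return self.statistic > self.critical


def class_areas(cmap: ClassRaster,
                pixel_area_ha: float = PIXEL_AREA_HA_30M,
                epoch: int = 0) -> AreaSummary:
    """Per-class areas of a class map; nodata pixels contribute nothing."""
    counts = cmap.class_counts()
    return AreaSummary(
        epoch=epoch,
        areas_ha={c: n * pixel_area_ha for c, n in counts.items()},
        pixel_area_ha=pixel_area_ha,
        pixel_counts=counts)


def percent_change(S_i: float, S_j: float) -> ChangeRecord:
    """Signed percent change (S_j − S_i)/S_i × 100 between two areas."""
    if not S_i > 0:
        raise ValueError("initial area S_i must be positive")
    return ChangeRecord(float(S_i), float(S_j))


def estimate_transition(map_t1: ClassRaster, map_t2: ClassRaster,
                        interval_years: float,
                        labels: tuple[int, ...] = CLASS_CODES,
                        ) -> tuple[TransitionCounts, TransitionMatrix]:
    """Estimate the Markov transition matrix from two dates.

    Cross-tabulates jointly classified pixels into n_ij and normalises each
    row: p_ij = n_ij / n_i.  A class absent at date 1 gets an identity row
    (the class persists) with a warning, keeping the matrix stochastic.
    """
    if map_t1.geometry != map_t2.geometry:
        raise RasterError("maps must be co-registered")
    joint = map_t1.valid & map_t2.valid
    if not joint.any():
        raise RasterError("no jointly classified pixels")
    q = len(labels)
    pos = {c: i for i, c in enumerate(labels)}
    i_idx = np.vectorize(pos.get)(map_t1.codes[joint])
    j_idx = np.vectorize(pos.get)(map_t2.codes[joint])
    n = np.bincount(i_idx * q + j_idx, minlength=q * q).reshape(q, q)

    p = np.zeros((q, q))
    for i in range(q):
        tot = n[i].sum()
        if tot == 0:
            warnings.warn(
                f"class {labels[i]} has no pixels at date 1; "
                "assigning an identity (persistence) row", stacklevel=2)
            p[i, i] = 1.0
        else:
            p[i] = n[i] / tot
    return TransitionCounts(n, labels), TransitionMatrix(p, interval_years, labels)


def _matrix_power(M: np.ndarray, exponent: float) -> np.ndarray:
    """Mʰ for integer or fractional h, repaired to row-stochastic form."""
    if float(exponent).is_integer():
        return np.linalg.matrix_power(M, int(round(exponent)))
    try:
        P = linalg.fractional_matrix_power(M, exponent)
    except Exception:  # non-diagonalizable corner
        warnings.warn("fractional matrix power failed; "
                      "falling back to nearest integer exponent", stacklevel=3)
        return np.linalg.matrix_power(M, int(round(exponent)))
    if np.iscomplexobj(P):
        if np.abs(P.imag).max() > 1e-8:
            warnings.warn("fractional matrix power has a significant "
                          "imaginary part; falling back to nearest integer "
                          "exponent", stacklevel=3)
            return np.linalg.matrix_power(M, int(round(exponent)))
        P = P.real
    P = np.clip(P, 0.0, None)
    rows = P.sum(axis=1, keepdims=True)
    rows[rows == 0] = 1.0
    return P / rows


def project_markov(v: ClassProportions, M: TransitionMatrix,
                   horizon_years: float) -> ClassProportions:
    """Project class proportions ``horizon_years`` ahead.

    The matrix is raised to h = horizon/interval (fractional h via the
    eigendecomposition power with clip-and-renormalise repair) and applied
    in the row-vector convention v' = v·Mʰ, so proportions stay a
    probability vector and total area is conserved.
    """
    if not horizon_years > 0:
        raise ValueError("horizon_years must be positive")
    exponent = horizon_years / M.interval_years
    Mh = _matrix_power(M.p, exponent)
    out = v.v @ Mh
    out = np.clip(out, 0.0, None)
    out = out / out.sum()
    return ClassProportions(out, v.total_area_ha, v.labels)


def project_series(v: ClassProportions, M: TransitionMatrix,
                   horizons_years) -> pd.DataFrame:
    """Tabulate projections for several horizons: one row per horizon per
    class with proportion and area in hectares."""
    rows = []
    for h in horizons_years:
        proj = project_markov(v, M, h)
        for c, p in zip(proj.labels, proj.v):
            rows.append({"horizon_years": h, "class": c,
                         "proportion": float(p),
                         "area_ha": float(p * proj.total_area_ha)})
    return pd.DataFrame(rows)


def stationary_distribution(M: TransitionMatrix) -> np.ndarray:
    """Long-run class proportions: the left eigenvector of M for eigenvalue 1,
    normalised to sum to 1."""
    w, vl = linalg.eig(M.p, left=True, right=False)
    k = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(vl[:, k])
    pi = np.abs(pi)
    return pi / pi.sum()


def chi_square_validate(observed, expected, q: int = 2,
                        alpha: float = 0.05) -> ChiSquareResult:
    """Pearson chi-squared goodness-of-fit between projected and observed
    per-class values.

    statistic = Σ (O−E)²/E with df = (q−1)² — for the two-class case a
    single degree of freedom and a critical value of 3.841 at α = 0.05.
    Rejection means the projection is statistically distinguishable from
    the observation at that level.
    """
    O = np.asarray(observed, dtype=float)
    E = np.asarray(expected, dtype=float)
    if O.shape != E.shape:
        raise ValueError("observed and expected must have the same shape")
    if (E <= 0).any():
        raise ValueError("all expected values must be positive")
    statistic = float(((O - E) ** 2 / E).sum())
    df = (q - 1) ** 2
    critical = float(stats.chi2.ppf(1.0 - alpha, df))
    return ChiSquareResult(statistic, df, critical, alpha)
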