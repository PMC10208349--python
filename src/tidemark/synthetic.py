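"""Synthetic multi-epoch landscapes with known Markov dynamics, rendered to
calibrated DN scenes.

The generator stands in for a multi-decadal satellite archive over a
mangrove coastline: a two-class landscape (mangrove / non-mangrove) evolves
between epochs by independent per-pixel transitions drawn from a known
row-stochastic matrix M*, and each epoch is rendered to 8-bit DN rasters by
drawing per-class Gaussian reflectance, inverting the TOA-reflectance
equation to radiance and the linear calibration to DN.  Because the whole
forward model is known, every pipeline stage has exact ground truth: the
calibration chain must invert the rendering, band selection must find the
designed SWIR1 contrast (mangrove canopies are dark in the short-wave
infrared), the classifier must recover the class maps, and transition
estimation must recover M* to within binomial sampling error.

Per-pixel transitions are deliberately aspatial — the Markov model being
tested is aspatial — with optional majority smoothing for visual realism
(off by default, since smoothing biases transition recovery).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .change import class_areas
from .radiometry import BandCalibration, SceneCalibration, write_mtl
from .raster import (BAND_LABELS, CLASS_CODES, MANGROVE, NON_MANGROVE,
                     BandRaster, ClassRaster, GridGeometry, MultiBandScene,
                     write_raster)

__all__ = ["SpectralSignature", "LandscapeConfig", "SyntheticTruth",
           "default_signatures", "default_calibration",
           "simulate_landscape_series", "render_scene", "make_fixture",
           "load_fixture_manifest", "DEFAULT_M"]

#: Default generating transition matrix (rows: from-class; moderately sticky
#: dynamics with net mangrove gain, stationary mix 2/3 : 1/3).
DEFAULT_M = np.array([[0.9, 0.1],
                      [0.2, 0.8]])


@dataclass
class SpectralSignature:
    """Per-class per-band Gaussian reflectance model.

    ``mean[class_code][band]`` and ``sd[class_code][band]`` in reflectance
    units; per-pixel draws are independent across pixels and bands and
    clipped to [0, 1].
    """

    mean: dict[int, dict[str, float]]
    sd: dict[int, dict[str, float]]

    def bands(self) -> list[str]:
        labs = set.intersection(*(set(m) for m in self.mean.values()))
        return [b for b in BAND_LABELS if b in labs]


def default_signatures(sd: float = 0.02) -> SpectralSignature:
    """Two-class signature set echoing the field contrast pattern.

    Mangrove is distinctively dark in SWIR1 (canopy water content) and
    bright in NIR; class-mean gaps shrink through Red, SWIR2, Green, Blue
    and are negligible in Thermal, so per-band separability ranks
    SWIR1 > NIR > Red > SWIR2 > visible/thermal at equal noise.
    """
    mangrove = {"Blue": 0.06, "Green": 0.09, "Red": 0.06, "NIR": 0.45,
                "SWIR1": 0.10, "SWIR2": 0.12, "Thermal": 0.31}
    other = {"Blue": 0.08, "Green": 0.12, "Red": 0.15, "NIR": 0.30,
             "SWIR1": 0.30, "SWIR2": 0.18, "Thermal": 0.32}
    return SpectralSignature(
        mean={MANGROVE: mangrove, NON_MANGROVE: other},
        sd={c: {b: sd for b in BAND_LABELS} for c in CLASS_CODES})


def default_calibration(theta_s: float = 30.0, d: float = 1.0,
                        bands=BAND_LABELS) -> SceneCalibration:
    """Landsat-flavoured calibration: per-band L_max set at the radiance of
    unit reflectance so the DN range spans exactly reflectance 0–1."""
    E0 = {"Blue": 1997.0, "Green": 1812.0, "Red": 1533.0, "NIR": 1039.0,
          "SWIR1": 230.8, "SWIR2": 84.9, "Thermal": 100.0}
    cos_t = np.cos(np.radians(theta_s))
    per_band = {}
    for b in bands:
        L_unit = E0[b] * cos_t / (np.pi * d * d)
        per_band[b] = BandCalibration(L_min=0.0, L_max=float(L_unit),
                                      Q_min=1, Q_max=255, E0=E0[b])
    return SceneCalibration(d=d, theta_s=theta_s, per_band=per_band)


@dataclass
class LandscapeConfig:
    """Generator settings.

    Defaults describe the benchmark condition used throughout the test
    suite: a 256×256 30 m grid (≈5900 ha), five epochs at a 5-year step,
    initial mangrove fraction 0.5, generating matrix ``DEFAULT_M``, no
    majority smoothing, no clouds.
    """

    n_rows: int = 256
    n_cols: int = 256
    initial_fraction: float = 0.5
    M: np.ndarray = field(default_factory=lambda: DEFAULT_M.copy())
    interval_years: float = 5.0
    n_epochs: int = 5
    start_year: int = 1988
    smoothing_passes: int = 0
    cloud_fraction: float = 0.0
    noise_sd_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=float)
        if not (0 <= self.initial_fraction <= 1):
            raise ValueError("initial_fraction must lie in [0, 1]")
        if not np.allclose(self.M.sum(axis=1), 1.0):
            raise ValueError("generating matrix must be row-stochastic")
        if self.n_rows < 2 or self.n_cols < 2:
            raise ValueError("landscape too small")

    @property
    def geometry(self) -> GridGeometry:
        return GridGeometry(self.n_rows, self.n_cols)

    @property
    def epochs(self) -> list[int]:
        return [int(self.start_year + k * self.interval_years)
                for k in range(self.n_epochs)]


@dataclass
class SyntheticTruth:
    """Everything the tests need to score the pipeline: the generating
    matrix, per-epoch class maps, signatures and exact class areas."""

    config: LandscapeConfig
    class_maps: list[ClassRaster]
    signatures: SpectralSignature
    cloud_masks: list[np.ndarray] = field(default_factory=list)

    def areas(self):
        return [class_areas(m, epoch=y)
                for m, y in zip(self.class_maps, self.config.epochs)]


def _initial_map(cfg: LandscapeConfig, rng: np.random.Generator) -> np.ndarray:
    """Spatially coherent starting landscape: threshold a smoothed Gaussian
    field at the quantile matching the target mangrove fraction."""
    fld = rng.standard_normal((cfg.n_rows, cfg.n_cols))
    fld = ndimage.gaussian_filter(fld, sigma=3.0)
    if cfg.initial_fraction <= 0:
        return np.full(fld.shape, NON_MANGROVE, dtype=np.uint8)
    if cfg.initial_fraction >= 1:
        return np.full(fld.shape, MANGROVE, dtype=np.uint8)
    cut = np.quantile(fld, cfg.initial_fraction)
    return np.where(fld <= cut, MANGROVE, NON_MANGROVE).astype(np.uint8)


def _majority_smooth(codes: np.ndarray, passes: int) -> np.ndarray:
    for _ in range(passes):
        mang = (codes == MANGROVE).astype(np.int8)
        neigh = ndimage.uniform_filter(mang.astype(float), size=3)
        codes = np.where(neigh > 0.5, MANGROVE, NON_MANGROVE).astype(np.uint8)
    return codes


def simulate_landscape_series(cfg: LandscapeConfig) -> SyntheticTruth:
    """Generate the epoch series of true class maps.

    Epoch 0 comes from a smoothed random field at the configured mangrove
    fraction; each later epoch applies independent per-pixel transitions
    with probabilities M*, then optional majority smoothing.  Deterministic
    given the seed.
    """
    rng = np.random.default_rng(cfg.seed)
    geom = cfg.geometry
    codes = _initial_map(cfg, rng)
    if cfg.smoothing_passes:
        codes = _majority_smooth(codes, cfg.smoothing_passes)
    maps = [ClassRaster(codes, geom)]
    for _ in range(1, cfg.n_epochs):
        u = rng.random(codes.shape)
        nxt = np.empty_like(codes)
        for ci, code in enumerate(CLASS_CODES):
            stay = u < cfg.M[ci, ci]
            here = codes == code
            other = CLASS_CODES[1 - ci]
            nxt[here] = np.where(stay[here], code, other)
        if cfg.smoothing_passes:
            nxt = _majority_smooth(nxt, cfg.smoothing_passes)
        codes = nxt
        maps.append(ClassRaster(codes, geom))

    masks = []
    for _ in range(cfg.n_epochs):
        if cfg.cloud_fraction > 0:
            masks.append(rng.random(codes.shape) < cfg.cloud_fraction)
        else:
            masks.append(np.zeros(codes.shape, dtype=bool))
    return SyntheticTruth(cfg, maps, default_signatures(), masks)


def render_scene(class_map: ClassRaster, sig: SpectralSignature,
                 cal: SceneCalibration, noise_sd_scale: float = 1.0,
                 seed: int = 0, sensor_id: str = "TM",
                 epoch: int = 0) -> MultiBandScene:
    """Render a class map to a DN scene through the inverse calibration.

    Per pixel and band, reflectance ~ N(mean_class, sd·scale) clipped to
    [0, 1], converted to radiance L = ρ·E0·cosθ/(π·d²), then to
    DN = (L − B)/G rounded and clipped to [Q_min, Q_max].  With zero noise
    each class renders to a single DN per band, so the scene is exactly
    separable.
    """
    rng = np.random.default_rng(seed)
    geom = class_map.geometry
    bands = {}
    for label in sig.bands():
        if label not in cal.per_band:
            raise KeyError(f"calibration lacks band {label}")
        bc = cal.per_band[label]
        rho = np.zeros(geom.shape)
        for code in CLASS_CODES:
            here = class_map.codes == code
            n = int(here.sum())
            mu = sig.mean[code][label]
            s = sig.sd[code][label] * noise_sd_scale
            draw = np.full(n, mu) if s == 0 else rng.normal(mu, s, size=n)
            rho[here] = np.clip(draw, 0.0, 1.0)
        L = rho * bc.E0 * cal.cos_theta / (np.pi * cal.d ** 2)
        dn = np.floor((L - bc.bias) / bc.gain + 0.5)
        dn = np.clip(dn, bc.Q_min, bc.Q_max).astype(np.int16)
        bands[label] = BandRaster(dn, geom, label,
                                  class_map.codes != 0)
    return MultiBandScene(bands, sensor_id=sensor_id, epoch=epoch,
                          calibration=cal)


def make_fixture(cfg: LandscapeConfig, out_dir) -> dict:
    """Write a complete on-disk fixture and its manifest.

    Layout: ``scenes/<epoch>/<band>.tif``, ``truth/<epoch>.tif``,
    ``masks/<epoch>.tif``, ``metadata/<epoch>.mtl``, ``manifest.json``.
    The manifest records seed, M*, signatures and exact areas — enough to
    regenerate the fixture bit-identically.
    """
    out = Path(out_dir)
    truth = simulate_landscape_series(cfg)
    cal = default_calibration()
    sig = truth.signatures
    manifest = {
        "seed": cfg.seed,
        "M": cfg.M.tolist(),
        "interval_years": cfg.interval_years,
        "epochs": cfg.epochs,
        "n_rows": cfg.n_rows, "n_cols": cfg.n_cols,
        "initial_fraction": cfg.initial_fraction,
        "smoothing_passes": cfg.smoothing_passes,
        "cloud_fraction": cfg.cloud_fraction,
        "noise_sd_scale": cfg.noise_sd_scale,
        "signature_mean": {str(c): sig.mean[c] for c in CLASS_CODES},
        "signature_sd": {str(c): sig.sd[c] for c in CLASS_CODES},
        "areas_ha": [], "scenes": {},
    }
    for k, (year, cmap, mask) in enumerate(
            zip(cfg.epochs, truth.class_maps, truth.cloud_masks)):
        (out / "truth").mkdir(parents=True, exist_ok=True)
        (out / "masks").mkdir(exist_ok=True)
        (out / "metadata").mkdir(exist_ok=True)
        scene_dir = out / "scenes" / str(year)
        scene_dir.mkdir(parents=True, exist_ok=True)

        write_raster(cmap, out / "truth" / f"{year}.tif")
        write_raster(BandRaster(mask.astype(np.int32), cmap.geometry,
                                "CloudMask"),
                     out / "masks" / f"{year}.tif")
        scene = render_scene(cmap, sig, cal, cfg.noise_sd_scale,
                             seed=cfg.seed + 1000 + k, epoch=year)
        for label, band in scene.bands.items():
            write_raster(band, scene_dir / f"{label}.tif")
        write_mtl(out / "metadata" / f"{year}.mtl", cal,
                  sensor_id=scene.sensor_id, year=year)
        summary = class_areas(cmap, epoch=year)
        manifest["areas_ha"].append(
            {"epoch": year, **{str(c): a for c, a in summary.areas_ha.items()}})
        manifest["scenes"][str(year)] = sorted(scene.bands)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def load_fixture_manifest(fixture_dir) -> dict:
    return json.loads((Path(fixture_dir) / "manifest.json").read_text())
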