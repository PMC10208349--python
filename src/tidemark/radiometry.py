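"""Sensor calibration: DN → radiance → TOA reflectance → DOS1 correction.

The chain mirrors the standard Landsat TM/ETM+ processing recipe:

1. DN to at-sensor spectral radiance, ``L = G·DN + B`` with gain
   ``G = (L_max − L_min)/(Q_max − Q_min)`` and bias ``B = L_min − G·Q_min``.
2. Radiance to top-of-atmosphere reflectance,
   ``ρ = π·L·d² / (E0·cos θ_s)`` with Earth–sun distance *d* in AU and solar
   zenith angle θ_s.
3. Dark-object subtraction (DOS1): the path radiance is estimated from the
   darkest population of the scene histogram assuming true dark objects
   reflect 1%, and subtracted from every cell:

   ``L_p = L_min + (L_max − L_min)/255 · DN_min
          − 0.01·(E0·cos θ_s·T_z + E_down)·T_v/π``

   with transmittances T_v = T_z = 1 and E_down = 0 in the simplest
   atmosphere.  Note the fixed 255 divisor in the haze term: it equals the
   DN gain only when Q_max − Q_min = 255, a quirk of the published recipe
   that is kept as-is (see the methods note).

Plus the NDVI water mask and optional 8-bit export scaling.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .raster import BandRaster, RasterError

__all__ = [
    "BandCalibration", "SceneCalibration", "Dos1Config",
    "dn_to_radiance", "radiance_to_toa", "dos1_correct",
    "ndvi_and_mask", "scale_to_8bit", "calibrate_band",
    "read_mtl", "write_mtl",
]


@dataclass(frozen=True)
class BandCalibration:
    """Radiometric rescaling constants for one band.

    L_min/L_max are the radiances (W m⁻² sr⁻¹ µm⁻¹) mapped to the DN
    endpoints Q_min/Q_max; E0 is the band's mean solar exoatmospheric
    irradiance (W m⁻² µm⁻¹).
    """

    L_min: float
    L_max: float
    Q_min: int = 1
    Q_max: int = 255
    E0: float = 1533.0

    def __post_init__(self) -> None:
        if not self.L_max > self.L_min:
            raise ValueError("L_max must exceed L_min")
        if not self.Q_max > self.Q_min:
            raise ValueError("Q_max must exceed Q_min")

    @property
    def gain(self) -> float:
        return (self.L_max - self.L_min) / (self.Q_max - self.Q_min)

    @property
    def bias(self) -> float:
        return self.L_min - self.gain * self.Q_min


@dataclass(frozen=True)
class SceneCalibration:
    """Scene-level solar geometry plus per-band rescaling constants.

    theta_s is the solar *zenith* angle in degrees (zenith = 90 − elevation);
    d is the Earth–sun distance in astronomical units.
    """

    d: float = 1.0
    theta_s: float = 30.0
    per_band: Mapping[str, BandCalibration] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.d > 0:
            raise ValueError("Earth-sun distance must be positive")
        if not (0 <= self.theta_s < 90):
            raise ValueError("solar zenith angle must lie in [0, 90)")

    @property
    def cos_theta(self) -> float:
        return math.cos(math.radians(self.theta_s))


@dataclass(frozen=True)
class Dos1Config:
    """DOS1 settings.

    dark_fraction is the histogram frequency fraction used to find DN_min
    (the smallest DN whose count reaches that fraction of the valid pixels);
    reflectance_floor is the assumed dark-object reflectance, 1% by
    convention.
    """

    T_v: float = 1.0
    T_z: float = 1.0
    E_down: float = 0.0
    dark_fraction: float = 0.0001
    reflectance_floor: float = 0.01

    def __post_init__(self) -> None:
        if not (0 < self.dark_fraction < 1):
            raise ValueError("dark_fraction must lie in (0, 1)")


def dn_to_radiance(dn: BandRaster, cal: BandCalibration) -> BandRaster:
    """Convert raw DN counts to at-sensor spectral radiance.

    Linear rescale ``L = G·DN + B``; maps Q_min → L_min and Q_max → L_max
    exactly.  Invalid cells stay invalid.
    """
    vals = dn.values.astype(np.float64)
    return dn.with_values(cal.gain * vals + cal.bias)


def radiance_to_toa(radiance: BandRaster, cal: BandCalibration,
                    scene: SceneCalibration) -> BandRaster:
    """At-sensor radiance to top-of-atmosphere reflectance.

    ρ = π·L·d² / (E0·cos θ_s).  Reflectance can exceed 1 over specular
    surfaces; no clipping happens here.
    """
    if not cal.E0 > 0:
        raise ValueError("E0 must be positive")
    factor = math.pi * scene.d ** 2 / (cal.E0 * scene.cos_theta)
    return radiance.with_values(radiance.values * factor)


def _dn_min(dn: BandRaster, dark_fraction: float) -> int:
    """Smallest DN whose histogram frequency reaches dark_fraction of the
    valid pixels — the haze estimate of the classic histogram method."""
    valid = dn.valid_values()
    if valid.size == 0:
        raise RasterError("DOS1 requires at least one valid cell")
    counts = np.asarray(valid, dtype=np.int64)
    values, freq = np.unique(counts, return_counts=True)
    threshold = dark_fraction * valid.size
    hit = values[freq >= threshold]
    # Degenerate: no single DN reaches the frequency cut — fall back to the
    # absolute darkest pixel.
    return int(hit[0]) if hit.size else int(values[0])


def dos1_correct(dn: BandRaster, cal: BandCalibration, scene: SceneCalibration,
                 cfg: Dos1Config | None = None) -> tuple[BandRaster, float]:
    """Dark-object path-radiance subtraction on a DN band.

    Returns the corrected radiance raster (floored at 0) and the scalar path
    radiance L_p.  A negative L_p — possible because the haze term uses a
    fixed /255 divisor — is applied as-is, i.e. radiance increases.
    """
    cfg = cfg or Dos1Config()
    dn_min = _dn_min(dn, cfg.dark_fraction)
    L = dn_to_radiance(dn, cal)
    L_p = (cal.L_min
           + (cal.L_max - cal.L_min) / 255.0 * dn_min
           - cfg.reflectance_floor
           * ((cal.E0 * scene.cos_theta * cfg.T_z) + cfg.E_down)
           * cfg.T_v / math.pi)
    if L_p < 0:
        warnings.warn(
            f"DOS1 path radiance is negative (L_p={L_p:.4f}); the fixed /255 "
            "divisor in the haze term can undershoot for very dark scenes",
            stacklevel=2)
    corrected = np.maximum(L.values - L_p, 0.0)
    return L.with_values(corrected), L_p


def calibrate_band(dn: BandRaster, cal: BandCalibration, scene: SceneCalibration,
                   cfg: Dos1Config | None = None) -> BandRaster:
    """Full chain DN → DOS1-corrected surface-proxy reflectance."""
    corrected, _ = dos1_correct(dn, cal, scene, cfg)
    return radiance_to_toa(corrected, cal, scene)


def ndvi_and_mask(nir: BandRaster, red: BandRaster,
                  threshold: float = 0.5) -> tuple[BandRaster, np.ndarray]:
    """NDVI = (NIR − Red)/(NIR + Red) and the water/ocean mask ndvi < threshold.

    Cells where NIR + Red = 0 are invalid in the NDVI raster and masked.
    The returned boolean grid is True where the cell should be discarded;
    whether it is applied scene-wide or only over a delineated ocean region
    is the caller's choice.
    """
    if nir.geometry != red.geometry:
        raise RasterError("NDVI requires co-registered bands")
    s = nir.values + red.values
    with np.errstate(divide="ignore", invalid="ignore"):
        ndvi = np.where(s != 0, (nir.values - red.values) / s, np.nan)
    valid = nir.validity_mask & red.validity_mask & (s != 0)
    out = BandRaster(ndvi, nir.geometry, "NDVI", valid)
    mask = ~valid | (np.nan_to_num(ndvi, nan=-np.inf) < threshold)
    return out, mask


def scale_to_8bit(reflectance: BandRaster) -> BandRaster:
    """Clip reflectance to [0, 1] and scale linearly to 0–255 (round half up).

    Export convenience only; classification consumes float reflectance.
    """
    clipped = np.clip(reflectance.values, 0.0, 1.0)
    scaled = np.floor(clipped * 255.0 + 0.5).astype(np.uint8)
    return BandRaster(scaled, reflectance.geometry, reflectance.band_label,
                      reflectance.validity_mask.copy())


# ---------------------------------------------------------------------------
# MTL-style metadata files
# ---------------------------------------------------------------------------
# Plain-text KEY = VALUE lines.  Per-band keys: <LABEL>_L_MIN, <LABEL>_L_MAX,
# <LABEL>_Q_MIN, <LABEL>_Q_MAX, <LABEL>_E0.  Scene keys: EARTH_SUN_DISTANCE,
# SUN_ZENITH or SUN_ELEVATION (zenith = 90 − elevation), SENSOR_ID, YEAR.

_BAND_KEY = re.compile(r"^(?P<band>[A-Za-z0-9]+)_(?P<field>L_MIN|L_MAX|Q_MIN|Q_MAX|E0)$")


def write_mtl(path, scene: SceneCalibration, sensor_id: str = "TM",
              year: int = 0) -> Path:
    path = Path(path)
    lines = [f"SENSOR_ID = {sensor_id}", f"YEAR = {year}",
             f"EARTH_SUN_DISTANCE = {scene.d!r}",
             f"SUN_ZENITH = {scene.theta_s!r}"]
    for label, bc in scene.per_band.items():
        lines += [f"{label}_L_MIN = {bc.L_min!r}", f"{label}_L_MAX = {bc.L_max!r}",
                  f"{label}_Q_MIN = {bc.Q_min}", f"{label}_Q_MAX = {bc.Q_max}",
                  f"{label}_E0 = {bc.E0!r}"]
    path.write_text("\n".join(lines) + "\n")
    return path


def read_mtl(path) -> tuple[SceneCalibration, str, int]:
    """Parse an MTL-style key-value file.

    Accepts either SUN_ZENITH or SUN_ELEVATION (converted as
    zenith = 90 − elevation).  Returns (SceneCalibration, sensor_id, year).
    """
    path = Path(path)
    scalars: dict[str, str] = {}
    bands: dict[str, dict[str, float]] = {}
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#") or "=" not in line:
            continue
        key, _, val = (p.strip() for p in line.partition("="))
        m = _BAND_KEY.match(key)
        if m:
            bands.setdefault(m["band"], {})[m["field"]] = float(val)
        else:
            scalars[key.upper()] = val

    if "SUN_ZENITH" in scalars:
        theta_s = float(scalars["SUN_ZENITH"])
    elif "SUN_ELEVATION" in scalars:
        theta_s = 90.0 - float(scalars["SUN_ELEVATION"])
    else:
        raise KeyError(f"{path}: needs SUN_ZENITH or SUN_ELEVATION")

    per_band = {
        label: BandCalibration(
            L_min=f["L_MIN"], L_max=f["L_MAX"],
            Q_min=int(f.get("Q_MIN", 1)), Q_max=int(f.get("Q_MAX", 255)),
            E0=f.get("E0", 1533.0))
        for label, f in bands.items()
    }
    scene = SceneCalibration(d=float(scalars.get("EARTH_SUN_DISTANCE", 1.0)),
                             theta_s=theta_s, per_band=per_band)
    return scene, scalars.get("SENSOR_ID", "TM"), int(scalars.get("YEAR", 0))
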