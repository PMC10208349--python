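"""Grid-aware raster containers and GeoTIFF I/O.

Every stage of the change-detection chain operates on co-registered grids:
continuous bands (DN counts, at-sensor radiance, or reflectance) and
categorical class maps.  Rasters follow the usual GeoTIFF convention — row 0
is the northernmost row and map coordinates refer to the upper-left corner of
the upper-left pixel, with half-open pixel extents.

Files are plain GeoTIFFs written through :mod:`tifffile` with the standard
georeferencing tags (ModelPixelScale, ModelTiepoint, GeoKeyDirectory) plus
the GDAL nodata convention, so they open in QGIS/GDAL unchanged.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import tifffile

#: Canonical band labels, ordered roughly by wavelength.
BAND_LABELS = ("Blue", "Green", "Red", "NIR", "SWIR1", "SWIR2", "Thermal")

#: Class codes used throughout: 0 = nodata, 1 = mangrove, 2 = non-mangrove.
NODATA, MANGROVE, NON_MANGROVE = 0, 1, 2
CLASS_CODES = (MANGROVE, NON_MANGROVE)

_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GEOKEYS = 34735
_TAG_GDAL_NODATA = 42113


class RasterError(ValueError):
    """Raised for malformed rasters or geometry mismatches."""


@dataclass(frozen=True)
class GridGeometry:
    """Pixel grid placed in map coordinates.

    Parameters
    ----------
    n_rows, n_cols
        Grid shape; both at least 1.
    pixel_size
        Ground sampling distance in metres (30 for Landsat-class imagery).
    origin
        ``(x, y)`` map coordinates of the upper-left corner of the
        upper-left pixel.
    crs_id
        Text identifier of the coordinate reference system, e.g. an
        ``"EPSG:32650"`` UTM zone code.
    """

    n_rows: int
    n_cols: int
    pixel_size: float = 30.0
    origin: tuple[float, float] = (0.0, 0.0)
    crs_id: str = "EPSG:32650"

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise RasterError("grid must have at least one row and column")
        if not self.pixel_size > 0:
            raise RasterError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def pixel_area_ha(self) -> float:
        """Area of one pixel in hectares (0.09 ha for a 30 m grid)."""
        return self.pixel_size * self.pixel_size / 10_000.0


@dataclass
class BandRaster:
    """One spectral band on a :class:`GridGeometry`.

    ``values`` may hold DN counts, radiance (W m⁻² sr⁻¹ µm⁻¹) or
    dimensionless reflectance; ``validity_mask`` is True where the cell
    carries data.  Invalid cells are excluded from every statistic.
    """

    values: np.ndarray
    geometry: GridGeometry
    band_label: str = "Red"
    validity_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.validity_mask is None:
            self.validity_mask = np.ones(self.values.shape, dtype=bool)
        self.validity_mask = np.asarray(self.validity_mask, dtype=bool)
        if self.values.shape != self.geometry.shape:
            raise RasterError(
                f"values shape {self.values.shape} != geometry {self.geometry.shape}"
            )
        if self.validity_mask.shape != self.values.shape:
            raise RasterError("validity_mask shape mismatch")

    @property
    def n_valid(self) -> int:
        return int(self.validity_mask.sum())

    def valid_values(self) -> np.ndarray:
        """1-D array of the values at valid cells."""
        return self.values[self.validity_mask]

    def with_values(self, values: np.ndarray) -> "BandRaster":
        """Same grid and mask, new cell values."""
        return BandRaster(values, self.geometry, self.band_label,
                          self.validity_mask.copy())


@dataclass
class ClassRaster:
    """Categorical map with codes 0 = nodata, 1 = mangrove, 2 = non-mangrove."""

    codes: np.ndarray
    geometry: GridGeometry

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.uint8)
        if self.codes.shape != self.geometry.shape:
            raise RasterError("codes shape does not match geometry")
        bad = set(np.unique(self.codes)) - {NODATA, *CLASS_CODES}
        if bad:
            raise RasterError(f"illegal class codes {sorted(bad)}")

    @property
    def valid(self) -> np.ndarray:
        return self.codes != NODATA

    def class_counts(self) -> dict[int, int]:
        """Pixel count per class code, nodata excluded."""
        return {c: int((self.codes == c).sum()) for c in CLASS_CODES}


@dataclass
class MultiBandScene:
    """Co-registered band stack for one epoch of one sensor."""

    bands: Mapping[str, BandRaster]
    sensor_id: str = "TM"
    epoch: int = 0
    calibration: object = None  # SceneCalibration; typed loosely to avoid a cycle

    def __post_init__(self) -> None:
        geoms = {b.geometry for b in self.bands.values()}
        if len(geoms) > 1:
            raise RasterError("all bands of a scene must share one geometry")

    @property
    def geometry(self) -> GridGeometry:
        return next(iter(self.bands.values())).geometry

    def joint_valid(self, band_labels=None) -> np.ndarray:
        """Boolean grid: cells valid in every listed band (all bands if None)."""
        labels = band_labels if band_labels is not None else list(self.bands)
        mask = np.ones(self.geometry.shape, dtype=bool)
        for lab in labels:
            mask &= self.bands[lab].validity_mask
        return mask


# ---------------------------------------------------------------------------
# GeoTIFF I/O
# ---------------------------------------------------------------------------

def _geotags(geom: GridGeometry, nodata: str) -> list:
    ps = float(geom.pixel_size)
    ox, oy = map(float, geom.origin)
    # Minimal GeoKeyDirectory: model type = projected, raster type = PixelIsArea.
    keys = (1, 1, 0, 2, 1024, 0, 1, 1, 1025, 0, 1, 1)
    return [
        (_TAG_PIXEL_SCALE, "d", 3, (ps, ps, 0.0), True),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, ox, oy, 0.0), True),
        (_TAG_GEOKEYS, "H", len(keys), keys, True),
        (_TAG_GDAL_NODATA, "s", 0, nodata, True),
    ]


def write_raster(raster: BandRaster | ClassRaster, path) -> Path:
    """Write a band or class raster as a georeferenced single-band GeoTIFF.

    Class maps are written as 8-bit integers with nodata = 0; float bands use
    NaN as the nodata sentinel, integer bands a declared sentinel (-9999).
    ``read_raster`` recovers values bit-exactly at the stored precision.
    """
    path = Path(path)
    geom = raster.geometry
    meta: dict = {"crs_id": geom.crs_id}
    if isinstance(raster, ClassRaster):
        data = raster.codes.astype(np.uint8)
        nodata = str(NODATA)
        meta["kind"] = "class"
    else:
        meta["kind"] = "band"
        meta["band_label"] = raster.band_label
        if np.issubdtype(raster.values.dtype, np.integer):
            sentinel = -9999
            data = raster.values.astype(np.int32, copy=True)
            data[~raster.validity_mask] = sentinel
            nodata = str(sentinel)
        else:
            data = raster.values.astype(np.float32, copy=True)
            data[~raster.validity_mask] = np.nan
            nodata = "nan"
    tifffile.imwrite(path, data, description=json.dumps(meta),
                     extratags=_geotags(geom, nodata))
    return path


def read_raster(path, band_label: str | None = None) -> BandRaster | ClassRaster:
    """Read a georeferenced GeoTIFF written by :func:`write_raster` (or any
    single-band GeoTIFF carrying pixel-scale and tiepoint tags).

    Returns a :class:`ClassRaster` if the file was written as a class map,
    else a :class:`BandRaster` with nodata cells flagged invalid.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        tags = page.tags
        if _TAG_PIXEL_SCALE not in tags or _TAG_TIEPOINT not in tags:
            raise RasterError(f"{path} lacks GeoTIFF georeferencing tags")
        ps = tags[_TAG_PIXEL_SCALE].value
        tp = tags[_TAG_TIEPOINT].value
        data = page.asarray()
        meta = {}
        if page.description:
            try:
                meta = json.loads(page.description)
            except (json.JSONDecodeError, TypeError):
                meta = {}
        nodata_raw = tags[_TAG_GDAL_NODATA].value if _TAG_GDAL_NODATA in tags else None

    geom = GridGeometry(
        n_rows=data.shape[0], n_cols=data.shape[1], pixel_size=float(ps[0]),
        origin=(float(tp[3]), float(tp[4])),
        crs_id=meta.get("crs_id", "unknown"),
    )
    if meta.get("kind") == "class":
        return ClassRaster(data, geom)

    if nodata_raw is None:
        mask = np.ones(data.shape, dtype=bool)
    else:
        try:
            sentinel = float(str(nodata_raw).strip())
        except ValueError:
            sentinel = None
        if sentinel is None:
            mask = np.ones(data.shape, dtype=bool)
        elif math.isnan(sentinel):
            mask = ~np.isnan(data)
        else:
            mask = data != sentinel
            if np.issubdtype(data.dtype, np.floating):
                mask &= ~np.isnan(data)
    label = band_label or meta.get("band_label", "Red")
    return BandRaster(data, geom, label, mask)


def apply_mask(raster: BandRaster, mask: np.ndarray) -> BandRaster:
    """Invalidate cells where ``mask`` is True (cloud, ocean, outside AOI).

    Valid cells keep their values untouched; already-invalid cells stay
    invalid.  Raises on shape mismatch.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != raster.values.shape:
        raise RasterError(
            f"mask shape {mask.shape} != raster shape {raster.values.shape}")
    return BandRaster(raster.values.copy(), raster.geometry, raster.band_label,
                      raster.validity_mask & ~mask)


def mask_class_raster(cr: ClassRaster, mask: np.ndarray) -> ClassRaster:
    """Set masked cells of a class map to nodata."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != cr.codes.shape:
        raise RasterError("mask shape mismatch")
    codes = cr.codes.copy()
    codes[mask] = NODATA
    return ClassRaster(codes, cr.geometry)
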