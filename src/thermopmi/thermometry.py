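"""Thermal-raster thermometry: ring-ROI extraction and instrument comparison.

Contact loggers obscure the skin directly beneath them in thermal images,
so the skin temperature at a logger site is taken as the mean over the
ring of pixels just outside the logger's border.  The module also provides
the paired statistics used to benchmark the two thermometer types
(contact loggers vs thermal camera) against each other.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

#: Values outside this physically plausible band are masked out.
PLAUSIBLE_RANGE_C = (-40.0, 60.0)


class RoiError(ValueError):
    """Ring ROI outside the raster or with too few usable pixels."""


@dataclass
class ThermalMap:
    """Raster of temperatures in deg C (pixel pitch arbitrary)."""

    values_C: np.ndarray
    timestamp: object = None

    def __post_init__(self):
        self.values_C = np.asarray(self.values_C, dtype=float)
        if self.values_C.ndim != 2:
            raise ValueError("thermal map must be a 2D raster")

    @property
    def mask(self) -> np.ndarray:
        """True where the pixel value is finite and physically plausible."""
        v = self.values_C
        return (np.isfinite(v) & (v >= PLAUSIBLE_RANGE_C[0])
                & (v <= PLAUSIBLE_RANGE_C[1]))

    @property
    def shape(self):
        return self.values_C.shape


@dataclass(frozen=True)
class RingROI:
    """Annulus of pixels around a logger, in pixel coordinates.

    ``cx`` is the column coordinate, ``cy`` the row coordinate; a pixel at
    (row, col) belongs to the ring when its centre distance to (cy, cx)
    lies in the half-open interval [r_inner, r_outer).
    """

    cx: float
    cy: float
    r_inner: float
    r_outer: float

    def __post_init__(self):
        if not 0 < self.r_inner < self.r_outer:
            raise ValueError("require 0 < r_inner < r_outer")


@dataclass
class RingStats:
    mean_C: float
    sd_C: float
    n_pixels: int


def extract_ring_temperature(tmap: ThermalMap, roi: RingROI,
                             min_pixels: int = 10) -> RingStats:
    """Mean/sd over unmasked pixels whose centres fall inside the ring."""
    n_rows, n_cols = tmap.shape
    if (roi.cx - roi.r_outer < -0.5 or roi.cy - roi.r_outer < -0.5
            or roi.cx + roi.r_outer > n_cols - 0.5
            or roi.cy + roi.r_outer > n_rows - 0.5):
        raise RoiError(f"ring (centre=({roi.cx}, {roi.cy}), "
                       f"r_outer={roi.r_outer}) exceeds raster {tmap.shape}")
    rows, cols = np.mgrid[0:n_rows, 0:n_cols]
    dist = np.hypot(cols - roi.cx, rows - roi.cy)
    in_ring = (dist >= roi.r_inner) & (dist < roi.r_outer) & tmap.mask
    n = int(in_ring.sum())
    if n < min_pixels:
        raise RoiError(f"only {n} usable pixels in ring (need {min_pixels})")
    vals = tmap.values_C[in_ring]
    sd = float(np.std(vals, ddof=1)) if n > 1 else 0.0
    return RingStats(float(vals.mean()), sd, n)


@dataclass
class ThermometerComparison:
    """Paired camera-vs-logger statistics.

    The difference sign convention is camera minus logger.  On constant
    series the Pearson correlation is undefined and flagged as such.
    """

    mean_difference_C: float
    sd_difference_C: float
    correlation: float
    n: int
    correlation_defined: bool = True


def compare_thermometers(pairs: Sequence[tuple]) -> ThermometerComparison:
    """Compare paired (logger_C, camera_C) readings."""
    data = np.asarray(list(pairs), dtype=float)
    if data.ndim != 2 or data.shape[1] != 2 or len(data) < 3:
        raise ValueError("need at least 3 (logger, camera) pairs")
    logger, camera = data[:, 0], data[:, 1]
    diff = camera - logger
    sd = float(np.std(diff, ddof=1))
    defined = np.std(logger) > 0 and np.std(camera) > 0
    if defined:
        r = float(np.corrcoef(logger, camera)[0, 1])
    else:
        r = float("nan")
    return ThermometerComparison(float(diff.mean()), sd, r, len(data),
                                 correlation_defined=bool(defined))


def load_thermal_map(path, gain: float = 1.0, offset: float = 0.0,
                     timestamp=None) -> ThermalMap:
    """Load a thermal raster.

    Plain CSV matrices hold deg C directly; 16-bit PNG/TIFF rasters are
    converted as ``gain * counts + offset`` (the linear scale from the
    exporter's sidecar header).
    """
    path = str(path)
    if path.endswith((".tif", ".tiff", ".png")):
        if path.endswith((".tif", ".tiff")):
            import tifffile
            counts = tifffile.imread(path).astype(float)
        else:
            from PIL import Image
            counts = np.asarray(Image.open(path), dtype=float)
        values = gain * counts + offset
    else:
        values = np.loadtxt(path, delimiter=",")
    return ThermalMap(values, timestamp)


def load_rois(path) -> dict:
    """Read ring ROIs from CSV: marker_id, cx, cy, r_inner, r_outer."""
    df = pd.read_csv(path)
    return {int(r.marker_id): RingROI(float(r.cx), float(r.cy),
                                      float(r.r_inner), float(r.r_outer))
            for r in df.itertuples()}
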