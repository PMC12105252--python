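"""Change metrics across scenarios and the hybridization-zone assessment.

The Standardized Connectivity Change Index (SCCI) compares cumulative
current between a current and a future scenario cell-wise::

    SCCI = (C_fut - C_cur) / (C_fut + C_cur)

bounded in [-1, +1]: +1 is a pure gain (no current today), -1 a total
loss, 0 corridor maintenance (cells where both are zero are set to 0 by
the same maintenance convention).  Percent connectivity change and
suitability-weighted centroid shifts summarize whole scenarios; the
hybridization assessment intersects two species ranges, buffers the
sympatry centroid and evaluates joint connectivity on the averaged
suitability of the two species.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from shapely.geometry import Point, Polygon

from .raster import Raster

__all__ = [
    "CentroidShift",
    "SympatryZone",
    "scci",
    "percent_connectivity_change",
    "weighted_centroid",
    "centroid_shift",
    "sympatry_zone",
    "average_sdms",
]


def scci(current: Raster, future: Raster) -> Raster:
    """Standardized Connectivity Change Index, cell-wise.

    Inputs are non-negative (cumulative current); both-zero cells map
    to 0 (corridor maintenance).
    """
    if not current.same_grid(future):
        raise ValueError("rasters are not co-registered")
    c = current.masked()
    f = future.masked()
    for v in (c, f):
        if np.nanmin(v) < 0:
            raise ValueError("current maps must be non-negative")
    denom = c + f
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, (f - c) / denom, 0.0)
    out[np.isnan(c) | np.isnan(f)] = np.nan
    return current.with_values(out, nodata=None)


def percent_connectivity_change(
    current: Raster, future: Raster, range_mask: np.ndarray
) -> float:
    """Percent change of mean cumulative current within a range mask:
    ``100 * (mean_fut - mean_cur) / mean_cur``."""
    mask = np.asarray(range_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty range mask")
    c = current.masked()[mask]
    f = future.masked()[mask]
    mc = np.nanmean(c)
    mf = np.nanmean(f)
    if mc == 0:
        raise ValueError("zero mean current connectivity inside the mask")
    return float(100.0 * (mf - mc) / mc)


def weighted_centroid(suitability: Raster) -> tuple[float, float]:
    """Suitability-weighted mean of cell-centre coordinates."""
    w = suitability.masked()
    w = np.where(np.isfinite(w), w, 0.0)
    total = w.sum()
    if total <= 0:
        raise ValueError("all-zero suitability raster has no centroid")
    X, Y = suitability.cell_centres()
    return float((w * X).sum() / total), float((w * Y).sum() / total)


@dataclass(frozen=True)
class CentroidShift:
    """Shift of the suitability-weighted centroid between two rasters."""

    current: tuple[float, float]
    future: tuple[float, float]
    distance: float
    azimuth: float  # degrees clockwise from grid north


def centroid_shift(current_sdm: Raster, future_sdm: Raster) -> CentroidShift:
    """Distance (map units) and compass azimuth of the centroid shift."""
    c = weighted_centroid(current_sdm)
    f = weighted_centroid(future_sdm)
    dx = f[0] - c[0]
    dy = f[1] - c[1]
    dist = float(np.hypot(dx, dy))
    az = float(np.degrees(np.arctan2(dx, dy)) % 360.0) if dist > 0 else 0.0
    return CentroidShift(current=c, future=f, distance=dist, azimuth=az)


@dataclass
class SympatryZone:
    """Overlap of two species ranges with a buffered contact area."""

    intersection: Polygon
    centroid: tuple[float, float]
    buffer: Polygon
    buffer_radius: float


def sympatry_zone(
    range_a: Polygon,
    range_b: Polygon,
    buffer_km: float = 50.0,
    map_units_per_km: float = 1000.0,
) -> SympatryZone:
    """Intersect two range polygons and buffer the sympatry centroid.

    The default radius of 50 km (map units = metres) is generous enough
    to contain the whole contact area.
    """
    inter = shapely.intersection(range_a, range_b)
    if inter.is_empty or inter.area == 0:
        raise ValueError("no sympatry: the ranges do not overlap")
    centroid = inter.centroid
    radius = buffer_km * map_units_per_km
    buf = centroid.buffer(radius, quad_segs=32)
    return SympatryZone(
        intersection=inter,
        centroid=(centroid.x, centroid.y),
        buffer=buf,
        buffer_radius=radius,
    )


def average_sdms(sdm_a: Raster, sdm_b: Raster, zone: SympatryZone | None = None) -> Raster:
    """Cell-wise arithmetic mean of two [0, 1] suitability rasters,
    optionally clipped (nodata outside) to the sympatry-zone buffer.

    A cell perfectly suitable for one species and useless for the other
    averages 0.5; suitable for both averages high — the joint layer for
    the hybridization connectivity run.
    """
    if not sdm_a.same_grid(sdm_b):
        raise ValueError("rasters are not co-registered")
    a = sdm_a.masked()
    b = sdm_b.masked()
    for v, label in ((a, "a"), (b, "b")):
        fin = v[np.isfinite(v)]
        if fin.size and (fin.min() < 0 or fin.max() > 1):
            raise ValueError(f"sdm_{label} values outside [0, 1]")
    out = (a + b) / 2.0
    if zone is not None:
        from .raster import rasterize_geometries

        inside = rasterize_geometries([zone.buffer], sdm_a)
        out = np.where(inside, out, np.nan)
    return sdm_a.with_values(out, nodata=None)
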