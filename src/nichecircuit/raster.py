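"""Raster data model, GeoTIFF I/O and grid utilities.

The :class:`Raster` is the carrier for every gridded quantity in the
pipeline: environmental predictors, suitability, resistance and current
maps.  Grids are row-major, north-up, cell-centre registered, in a
projected CRS with map units (no geographic lat/long support).

The affine georeference follows the GDAL/rasterio convention
``(a, b, c, d, e, f)``::

    x = a * col + b * row + c
    y = d * col + e * row + f

with ``b = d = 0`` (axis-aligned grids only) and ``e < 0`` (row 0 is the
northernmost row).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

__all__ = [
    "Raster",
    "RasterStack",
    "read_geotiff",
    "write_geotiff",
    "read_stack",
    "write_stack",
    "slope_aspect",
    "euclidean_distance",
    "filter_streams",
    "resample",
    "vif_screen",
    "extract_at_points",
    "thin_occurrences",
    "rasterize_geometries",
]

_UNSET = object()

# TIFF tag ids used for minimal GeoTIFF compliance
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


@dataclass(frozen=True)
class Raster:
    """A single-band georeferenced grid.

    Parameters
    ----------
    values : ndarray
        2-D array, row 0 = north.
    transform : tuple of 6 floats
        Affine georeference ``(a, b, c, d, e, f)``; see module docstring.
    crs : str
        CRS identifier; a plain label for the synthetic projected CRS.
    nodata : float or None
        Sentinel value excluded from all statistics.
    """

    values: np.ndarray
    transform: tuple[float, float, float, float, float, float]
    crs: str = "local-projected"
    nodata: float | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2:
            raise ValueError(f"Raster values must be 2-D, got shape {v.shape}")
        a, b, c, d, e, f = self.transform
        if b != 0 or d != 0:
            raise ValueError("only axis-aligned grids are supported")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "transform", tuple(float(t) for t in self.transform))

    # ---- geometry -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def cell_size(self) -> float:
        """Cell size in map units (square cells assumed)."""
        return abs(self.transform[0])

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the full extent (cell edges)."""
        a, _, c, _, e, f = self.transform
        nrows, ncols = self.shape
        xs = sorted((c, c + a * ncols))
        ys = sorted((f, f + e * nrows))
        return xs[0], ys[0], xs[1], ys[1]

    def xy(self, row, col):
        """Map coordinates of cell centres."""
        a, _, c, _, e, f = self.transform
        return c + a * (np.asarray(col) + 0.5), f + e * (np.asarray(row) + 0.5)

    def index(self, x, y):
        """(row, col) of the cells containing map coordinates."""
        a, _, c, _, e, f = self.transform
        col = np.floor((np.asarray(x, dtype=float) - c) / a).astype(int)
        row = np.floor((np.asarray(y, dtype=float) - f) / e).astype(int)
        return row, col

    def contains(self, x, y):
        xmin, ymin, xmax, ymax = self.bounds
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (x >= xmin) & (x < xmax) & (y > ymin) & (y <= ymax)

    def cell_centres(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrids (X, Y) of all cell-centre coordinates."""
        nrows, ncols = self.shape
        cols, rows = np.meshgrid(np.arange(ncols), np.arange(nrows))
        return self.xy(rows, cols)

    # ---- values ---------------------------------------------------
    def valid_mask(self) -> np.ndarray:
        m = np.isfinite(self.values.astype(float))
        if self.nodata is not None:
            m &= self.values != self.nodata
        return m

    def masked(self) -> np.ndarray:
        """Values with nodata replaced by NaN (float copy)."""
        out = self.values.astype(float).copy()
        out[~self.valid_mask()] = np.nan
        return out

    def with_values(self, values: np.ndarray, nodata=_UNSET) -> "Raster":
        if values.shape != self.shape:
            raise ValueError("shape mismatch")
        nd = self.nodata if nodata is _UNSET else nodata
        return Raster(values, self.transform, self.crs, nd)

    def same_grid(self, other: "Raster") -> bool:
        return self.shape == other.shape and np.allclose(
            self.transform, other.transform
        )

    @staticmethod
    def from_origin(values, x0: float, y_top: float, cell: float, crs="local-projected", nodata=None):
        """Build a raster from its north-west corner and cell size."""
        return Raster(values, (cell, 0.0, x0, 0.0, -cell, y_top), crs, nodata)


class RasterStack:
    """An ordered, name-keyed collection of co-registered rasters."""

    def __init__(self, layers: Mapping[str, Raster]):
        items = list(layers.items())
        if not items:
            raise ValueError("empty stack")
        first = items[0][1]
        for name, r in items[1:]:
            if not first.same_grid(r):
                raise ValueError(f"layer {name!r} is not on the stack grid")
        self._layers = dict(items)

    @property
    def names(self) -> list[str]:
        return list(self._layers)

    @property
    def grid(self) -> Raster:
        return next(iter(self._layers.values()))

    def __getitem__(self, name: str) -> Raster:
        return self._layers[name]

    def __contains__(self, name: str) -> bool:
        return name in self._layers

    def __iter__(self) -> Iterator[str]:
        return iter(self._layers)

    def __len__(self) -> int:
        return len(self._layers)

    def items(self):
        return self._layers.items()

    def subset(self, names: Sequence[str]) -> "RasterStack":
        return RasterStack({n: self._layers[n] for n in names})

    def to_array(self) -> np.ndarray:
        """(n_layers, rows, cols) float array with NaN for nodata."""
        return np.stack([r.masked() for r in self._layers.values()])

    def valid_mask(self) -> np.ndarray:
        m = np.ones(self.grid.shape, dtype=bool)
        for r in self._layers.values():
            m &= r.valid_mask()
        return m

    def table(self) -> pd.DataFrame:
        """All cells as rows (NaN for nodata), column per layer."""
        return pd.DataFrame(
            {n: r.masked().ravel() for n, r in self._layers.items()}
        )


# ---------------------------------------------------------------- I/O

def write_geotiff(raster: Raster, path) -> None:
    """Write a single-band GeoTIFF (pixel scale, tiepoint and nodata tags)."""
    _write_pages(path, [raster.values], raster, names=None)


def read_geotiff(path) -> Raster:
    rasters, _ = _read_pages(path)
    return rasters[0]


def write_stack(stack: RasterStack, path) -> None:
    """Write a multi-band GeoTIFF; band names stored in the description."""
    grid = stack.grid
    _write_pages(path, [stack[n].values for n in stack.names], grid, stack.names)


def read_stack(path) -> RasterStack:
    rasters, names = _read_pages(path)
    if names is None:
        names = [f"band_{i + 1}" for i in range(len(rasters))]
    return RasterStack(dict(zip(names, rasters)))


def _write_pages(path, arrays, grid: Raster, names) -> None:
    a, _, c, _, e, f = grid.transform
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (abs(a), abs(e), 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, c, f, 0.0)),
    ]
    if grid.nodata is not None:
        nd = repr(float(grid.nodata))
        extratags.append((_TAG_GDAL_NODATA, "s", len(nd) + 1, nd))
    desc = json.dumps({"crs": grid.crs, "names": names})
    with tifffile.TiffWriter(path) as tif:
        for arr in arrays:
            tif.write(
                np.ascontiguousarray(arr),
                description=desc,
                extratags=extratags,
                photometric="minisblack",
            )


def _read_pages(path):
    rasters: list[Raster] = []
    names = None
    with tifffile.TiffFile(path) as tif:
        for page in tif.pages:
            values = page.asarray()
            scale = page.tags[_TAG_MODEL_PIXEL_SCALE].value
            tie = page.tags[_TAG_MODEL_TIEPOINT].value
            nodata = None
            if _TAG_GDAL_NODATA in page.tags:
                nodata = float(page.tags[_TAG_GDAL_NODATA].value.rstrip("\x00"))
            crs = "local-projected"
            if page.description:
                try:
                    meta = json.loads(page.description)
                    crs = meta.get("crs", crs)
                    names = meta.get("names", names)
                except (ValueError, AttributeError):
                    pass
            transform = (scale[0], 0.0, tie[3], 0.0, -scale[1], tie[4])
            rasters.append(Raster(values, transform, crs, nodata))
    return rasters, names


# ------------------------------------------------- terrain derivatives

def slope_aspect(dem: Raster, aspect_nodata: float = -1.0) -> tuple[Raster, Raster]:
    """Slope and aspect by Horn's 3x3 method.

    Slope in degrees [0, 90]; aspect in degrees [0, 360) clockwise from
    north, pointing downslope; flat cells get ``aspect_nodata``.  Edge
    cells use nearest-neighbour padding.
    """
    z = dem.masked()
    if np.isnan(z).any():
        raise ValueError("slope_aspect requires a gap-free DEM")
    cell = dem.cell_size
    zp = np.pad(z, 1, mode="edge")
    # 3x3 neighbourhood, rows north-up: n=row-1, s=row+1, e=col+1, w=col-1
    nw, n_, ne = zp[:-2, :-2], zp[:-2, 1:-1], zp[:-2, 2:]
    w_, e_ = zp[1:-1, :-2], zp[1:-1, 2:]
    sw, s_, se = zp[2:, :-2], zp[2:, 1:-1], zp[2:, 2:]
    dzdx = ((ne + 2 * e_ + se) - (nw + 2 * w_ + sw)) / (8 * cell)
    dzdy = ((nw + 2 * n_ + ne) - (sw + 2 * s_ + se)) / (8 * cell)  # northward
    slope = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
    # azimuth of the downslope direction, clockwise from north
    aspect = np.degrees(np.arctan2(-dzdx, -dzdy)) % 360.0
    flat = (dzdx == 0) & (dzdy == 0)
    aspect[flat] = aspect_nodata
    return (
        dem.with_values(slope, nodata=None),
        dem.with_values(aspect, nodata=aspect_nodata),
    )


def euclidean_distance(mask: np.ndarray, grid: Raster) -> Raster:
    """Distance (map units) from each cell centre to the nearest feature
    cell centre; 0 on feature cells."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != grid.shape:
        raise ValueError("mask shape does not match grid")
    if not mask.any():
        raise ValueError("empty feature mask")
    cell = grid.cell_size
    dist = ndimage.distance_transform_edt(~mask, sampling=cell)
    return grid.with_values(dist, nodata=None)


def filter_streams(streams, max_order: int = 3):
    """Retain stream segments whose Strahler order is <= ``max_order``.

    ``streams`` is a sequence of objects (e.g. StreamSegment) with an
    integer ``order`` attribute.
    """
    out = []
    for seg in streams:
        order = getattr(seg, "order", None)
        if order is None:
            raise ValueError("stream segment missing Strahler order")
        if order <= max_order:
            out.append(seg)
    return out


# ------------------------------------------------------------ resample

def resample(r: Raster, target_cell: float, method: str = "bilinear") -> Raster:
    """Resample to a new cell size on the same extent origin.

    ``bilinear`` for continuous layers, ``nearest`` for categorical.
    """
    if target_cell <= 0:
        raise ValueError("target_cell must be positive")
    if method not in ("nearest", "bilinear"):
        raise ValueError(f"unknown resampling method: {method!r}")
    a, _, c, _, e, f = r.transform
    xmin, ymin, xmax, ymax = r.bounds
    ncols = max(1, int(round((xmax - xmin) / target_cell)))
    nrows = max(1, int(round((ymax - ymin) / target_cell)))
    out_transform = (target_cell, 0.0, c, 0.0, -target_cell, f)
    # fractional source indices of target cell centres
    xs = c + target_cell * (np.arange(ncols) + 0.5)
    ys = f - target_cell * (np.arange(nrows) + 0.5)
    col_idx = (xs - c) / a - 0.5
    row_idx = (ys - f) / e - 0.5
    cc, rr = np.meshgrid(col_idx, row_idx)
    order = 0 if method == "nearest" else 1
    vals = ndimage.map_coordinates(
        r.values.astype(float), [rr, cc], order=order, mode="nearest"
    )
    if method == "nearest" and np.issubdtype(r.values.dtype, np.integer):
        vals = np.round(vals).astype(r.values.dtype)
    return Raster(vals, out_transform, r.crs, r.nodata)


# ------------------------------------------------------- VIF screening

def vif_screen(
    stack: RasterStack,
    threshold: float = 10.0,
    max_cells: int = 10_000,
    seed: int = 0,
) -> tuple[list[str], list[tuple[str, float]]]:
    """Iterative variance-inflation-factor screening of predictor layers.

    Repeatedly drops the layer with the largest VIF (``1 / (1 - R^2)``
    from regressing it on all the others) until every VIF is below
    ``threshold``.  Ties break by layer-name order.  Computed on a
    random sample of at most ``max_cells`` jointly valid cells.

    Returns ``(retained_names, drop_log)`` where the log holds
    ``(name, vif_at_drop)`` in drop order.
    """
    if len(stack) < 2:
        raise ValueError("need at least two layers")
    valid = stack.valid_mask()
    idx = np.flatnonzero(valid.ravel())
    rng = np.random.default_rng(seed)
    if idx.size > max_cells:
        idx = rng.choice(idx, size=max_cells, replace=False)
    data = {n: stack[n].masked().ravel()[idx] for n in stack.names}
    remaining = sorted(stack.names)
    dropped: list[tuple[str, float]] = []
    while len(remaining) > 1:
        vifs = {n: _vif_of(data, n, remaining) for n in remaining}
        # max() keeps the first of equal keys; `remaining` is name-sorted,
        # so ties break by layer-name order
        worst = max(remaining, key=lambda n: vifs[n])
        if vifs[worst] < threshold:
            break
        remaining.remove(worst)
        dropped.append((worst, vifs[worst]))
    retained = [n for n in stack.names if n in remaining]
    return retained, dropped


def _vif_of(data: dict, name: str, remaining: list[str]) -> float:
    y = data[name]
    others = [n for n in remaining if n != name]
    X = np.column_stack([data[n] for n in others] + [np.ones_like(y)])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        return np.inf
    r2 = 1.0 - ss_res / ss_tot
    if r2 >= 1.0 - 1e-12:
        return np.inf
    return 1.0 / (1.0 - r2)


# ----------------------------------------------------- point utilities

def extract_at_points(stack: RasterStack, pts: pd.DataFrame) -> pd.DataFrame:
    """Predictor values at point locations; one row per point.

    ``pts`` needs ``x`` and ``y`` columns.  Nodata cells propagate NaN
    and set the ``missing`` flag.  Points outside the extent raise,
    listing the offenders.
    """
    grid = stack.grid
    inside = grid.contains(pts["x"].to_numpy(), pts["y"].to_numpy())
    if not inside.all():
        bad = pts.loc[~inside, ["x", "y"]]
        raise ValueError(f"points outside raster extent:\n{bad}")
    row, col = grid.index(pts["x"].to_numpy(), pts["y"].to_numpy())
    out = pd.DataFrame(index=pts.index)
    for name in stack.names:
        out[name] = stack[name].masked()[row, col]
    out["missing"] = out[stack.names].isna().any(axis=1)
    return out


def thin_occurrences(pts: pd.DataFrame, grid: Raster) -> pd.DataFrame:
    """Spatial thinning: keep at most one point per grid cell per species.

    Retention is deterministic — first point after a stable sort on
    (x, y) within each cell.
    """
    if pts.empty:
        return pts.copy()
    pts = pts.sort_values(["x", "y"], kind="stable")
    row, col = grid.index(pts["x"].to_numpy(), pts["y"].to_numpy())
    keys = pd.DataFrame({"row": row, "col": col}, index=pts.index)
    if "species" in pts.columns:
        keys["species"] = pts["species"].to_numpy()
    keep = ~keys.duplicated()
    return pts.loc[keep].reset_index(drop=True)


# --------------------------------------------------------- rasterizing

def rasterize_geometries(geoms, grid: Raster, all_touched_radius: float | None = None) -> np.ndarray:
    """Boolean mask of cells covered by shapely geometries.

    Polygons mark cells whose centre they contain; lines (and points)
    mark cells whose centre lies within half a cell of the geometry
    (``all_touched_radius`` overrides that radius).
    """
    import shapely

    X, Y = grid.cell_centres()
    pts = shapely.points(X.ravel(), Y.ravel())
    mask = np.zeros(X.size, dtype=bool)
    radius = grid.cell_size / 2.0 if all_touched_radius is None else all_touched_radius
    for geom in geoms:
        if geom is None or geom.is_empty:
            continue
        if geom.geom_type in ("Polygon", "MultiPolygon"):
            mask |= shapely.contains_xy(geom, X.ravel(), Y.ravel())
        else:
            mask |= shapely.dwithin(geom, pts, radius)
    return mask.reshape(grid.shape)
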