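"""Synthetic landscapes and virtual species with known ground truth.

Every downstream stage of the pipeline (niche models, fine-scale
overlay, connectivity) is exercised on landscapes generated here, so
that truth is known exactly: spatially autocorrelated climate fields
with per-scenario additive deltas, a DEM with a derived stream network
(Strahler-ordered), scattered water points, road/urban barrier
geometries, and virtual-species occurrences sampled from a known
suitability surface.

All generation is deterministic under a fixed seed: the same
:class:`LandscapeConfig` always yields bit-identical rasters and point
sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LineString, Point, Polygon

from .raster import Raster, RasterStack, euclidean_distance

__all__ = [
    "LandscapeConfig",
    "StreamSegment",
    "VirtualSpecies",
    "gaussian_random_field",
    "generate_climate_stack",
    "generate_dem",
    "generate_habitat",
    "generate_hydrology",
    "generate_barriers",
    "make_virtual_species",
    "sample_occurrences",
    "generate_landscape",
]


@dataclass(frozen=True)
class LandscapeConfig:
    """Parameters of a synthetic landscape.

    ``scenario_deltas`` maps a scenario id (e.g. ``"2050_ssp245_gcm1"``)
    to per-climate-variable additive shifts, either a scalar applied to
    every variable or a mapping ``variable name -> shift``.
    """

    grid_shape: tuple[int, int] = (120, 120)
    cell_size: float = 100.0
    n_climate_vars: int = 4
    autocorr_range: float = 2000.0
    seed: int = 42
    scenario_deltas: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        r, c = self.grid_shape
        if r <= 0 or c <= 0:
            raise ValueError("grid_shape must be positive")
        if self.autocorr_range <= 0:
            raise ValueError("autocorr_range must be positive")
        if self.n_climate_vars < 1:
            raise ValueError("need at least one climate variable")

    def blank_grid(self) -> Raster:
        r, c = self.grid_shape
        return Raster.from_origin(
            np.zeros((r, c)), 0.0, r * self.cell_size, self.cell_size
        )


@dataclass
class StreamSegment:
    """A stream polyline between junctions, with its Strahler order."""

    coords: list[tuple[float, float]]
    order: int

    @property
    def geometry(self) -> LineString:
        if len(self.coords) == 1:
            # degenerate one-cell reach; represent as a tiny segment
            (x, y) = self.coords[0]
            return LineString([(x, y), (x, y)])
        return LineString(self.coords)


@dataclass
class VirtualSpecies:
    """A species whose suitability over the landscape is known exactly."""

    name: str
    suitability_fn: Callable[[pd.DataFrame], np.ndarray]
    true_suitability: Raster
    n_occurrences: int = 128


# ------------------------------------------------ Gaussian random field

def gaussian_random_field(
    shape: tuple[int, int],
    cell_size: float,
    corr_range: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Zero-mean, unit-variance field with exponential covariance
    ``exp(-h / corr_range)``, by spectral filtering of white noise.

    The radial spectral density of the 2-D exponential covariance with
    e-folding length L is ``S(f) = 2 pi L^2 (1 + (2 pi L f)^2)^(-3/2)``
    (f in cycles per map unit).  The domain is padded by ~4 correlation
    lengths to suppress periodic wrap-around, then cropped.
    """
    nrows, ncols = shape
    pad = int(np.ceil(4 * corr_range / cell_size))
    nr, nc = nrows + pad, ncols + pad
    fy = np.fft.fftfreq(nr, d=cell_size)
    fx = np.fft.fftfreq(nc, d=cell_size)
    f = np.hypot(*np.meshgrid(fx, fy))
    L = corr_range
    spec = 2 * np.pi * L**2 * (1 + (2 * np.pi * L * f) ** 2) ** (-1.5)
    noise = rng.standard_normal((nr, nc))
    fld = np.fft.ifft2(np.fft.fft2(noise) * np.sqrt(spec)).real
    fld = fld[:nrows, :ncols]
    fld -= fld.mean()
    sd = fld.std()
    if sd > 0:
        fld /= sd
    return fld


# -------------------------------------------------------- climate stack

def _climate_layer(cfg: LandscapeConfig, i: int, rng: np.random.Generator) -> np.ndarray:
    nrows, ncols = cfg.grid_shape
    rows, cols = np.meshgrid(
        np.arange(nrows), np.arange(ncols), indexing="ij"
    )
    # smooth large-scale gradient: alternate latitudinal / longitudinal
    if i % 2 == 0:
        grad = (nrows - 1 - rows) / max(nrows - 1, 1)  # increases northward
    else:
        grad = cols / max(ncols - 1, 1)  # increases eastward
    fld = gaussian_random_field(cfg.grid_shape, cfg.cell_size, cfg.autocorr_range, rng)
    return 1.5 * (grad - grad.mean()) + fld


def generate_climate_stack(cfg: LandscapeConfig) -> dict[str, RasterStack]:
    """Climate predictor stacks keyed by scenario; ``"present"`` plus one
    stack per entry of ``cfg.scenario_deltas``.

    Future layers are the present layers plus the scenario's additive
    per-variable shift; all layers share grid and CRS.
    """
    rng = np.random.default_rng(cfg.seed)
    grid = cfg.blank_grid()
    names = [f"clim_{i + 1}" for i in range(cfg.n_climate_vars)]
    present = {
        n: grid.with_values(_climate_layer(cfg, i, rng))
        for i, n in enumerate(names)
    }
    out = {"present": RasterStack(present)}
    for scen, deltas in cfg.scenario_deltas.items():
        layers = {}
        for n in names:
            if isinstance(deltas, Mapping):
                shift = float(deltas.get(n, 0.0))
            else:
                shift = float(deltas)
            layers[n] = present[n].with_values(present[n].values + shift)
        out[scen] = RasterStack(layers)
    return out


# ---------------------------------------------------------------- DEM

def generate_dem(cfg: LandscapeConfig, relief: float = 400.0) -> Raster:
    """A DEM descending roughly southward with autocorrelated relief."""
    rng = np.random.default_rng(cfg.seed + 1_000)
    nrows, ncols = cfg.grid_shape
    rows = np.arange(nrows)[:, None] * np.ones((1, ncols))
    base = (nrows - 1 - rows) / max(nrows - 1, 1)  # high in the north
    rough = gaussian_random_field(cfg.grid_shape, cfg.cell_size, cfg.autocorr_range, rng)
    z = relief * (1.5 * base + 0.35 * rough)
    return cfg.blank_grid().with_values(z)


def generate_habitat(cfg: LandscapeConfig, n_classes: int = 4) -> Raster:
    """Categorical habitat-class raster (quantile slices of a smooth field)."""
    rng = np.random.default_rng(cfg.seed + 2_000)
    fld = gaussian_random_field(cfg.grid_shape, cfg.cell_size, cfg.autocorr_range, rng)
    qs = np.quantile(fld, np.linspace(0, 1, n_classes + 1)[1:-1])
    classes = np.digitize(fld, qs).astype(np.int32)
    return cfg.blank_grid().with_values(classes)


# ----------------------------------------------------------- hydrology

_D8_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _fill_depressions(z: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Priority-flood depression filling so every cell drains to the
    boundary; a tiny epsilon gradient keeps filled flats drainable."""
    import heapq

    nrows, ncols = z.shape
    filled = np.full(z.shape, np.inf)
    visited = np.zeros(z.shape, dtype=bool)
    heap: list[tuple[float, int, int]] = []
    for r in range(nrows):
        for c in (0, ncols - 1):
            heapq.heappush(heap, (z[r, c], r, c))
            visited[r, c] = True
    for c in range(ncols):
        for r in (0, nrows - 1):
            if not visited[r, c]:
                heapq.heappush(heap, (z[r, c], r, c))
                visited[r, c] = True
    while heap:
        zc, r, c = heapq.heappop(heap)
        filled[r, c] = zc
        for dr, dc in _D8_OFFSETS:
            rr, cc = r + dr, c + dc
            if 0 <= rr < nrows and 0 <= cc < ncols and not visited[rr, cc]:
                visited[rr, cc] = True
                heapq.heappush(heap, (max(z[rr, cc], zc + eps), rr, cc))
    return filled


def _d8_downstream(z: np.ndarray) -> np.ndarray:
    """Index (flattened) of the steepest-descent neighbour; -1 = outlet."""
    nrows, ncols = z.shape
    down = np.full(z.shape, -1, dtype=np.int64)
    best_drop = np.zeros(z.shape)
    for dr, dc in _D8_OFFSETS:
        dist = np.hypot(dr, dc)
        shifted = np.full(z.shape, np.inf)
        r0, r1 = max(dr, 0), nrows + min(dr, 0)
        c0, c1 = max(dc, 0), ncols + min(dc, 0)
        shifted[r0 - dr : r1 - dr, c0 - dc : c1 - dc] = z[r0:r1, c0:c1]
        drop = (z - shifted) / dist
        better = drop > best_drop
        rows, cols = np.nonzero(better)
        down[better] = (rows + dr) * ncols + (cols + dc)
        best_drop = np.where(better, drop, best_drop)
    return down


def generate_hydrology(
    cfg: LandscapeConfig,
    dem: Raster,
    accumulation_threshold: int = 40,
    water_density: float = 2e-7,
) -> tuple[list[StreamSegment], list[Point]]:
    """Stream network (D8 flow over the DEM) and scattered water points.

    Streams are the cells whose D8 flow accumulation reaches
    ``accumulation_threshold`` cells; Strahler order follows the
    standard junction rule (equal-order confluence increments, else the
    max propagates).  Water points emulate the pools/springs database,
    scattered uniformly with ``water_density`` points per square map
    unit.
    """
    z = dem.values.astype(float)
    if np.ptp(z) == 0:
        raise ValueError("flat DEM: degenerate stream network")
    z = _fill_depressions(z)
    nrows, ncols = z.shape
    down = _d8_downstream(z).ravel()
    order_by_z = np.argsort(z.ravel())[::-1]  # high to low
    acc = np.ones(z.size, dtype=np.int64)
    for i in order_by_z:
        d = down[i]
        if d >= 0:
            acc[d] += acc[i]
    stream = acc >= accumulation_threshold
    if not stream.any():
        raise ValueError(
            "degenerate stream network: no cell reaches the accumulation threshold"
        )
    # Strahler order per stream cell, processed downslope
    strahler = np.zeros(z.size, dtype=np.int64)
    inflows: dict[int, list[int]] = {}
    for i in order_by_z:
        if not stream[i]:
            continue
        ups = inflows.get(i, [])
        if not ups:
            strahler[i] = 1
        else:
            omax = max(strahler[u] for u in ups)
            ties = sum(1 for u in ups if strahler[u] == omax)
            strahler[i] = omax + 1 if ties >= 2 else omax
        d = down[i]
        if d >= 0 and stream[d]:
            inflows.setdefault(d, []).append(i)
    segments = _extract_segments(dem, stream, down, strahler, inflows, order_by_z)
    # water points
    rng = np.random.default_rng(cfg.seed + 3_000)
    xmin, ymin, xmax, ymax = dem.bounds
    area = (xmax - xmin) * (ymax - ymin)
    n_pts = max(1, rng.poisson(water_density * area))
    pts = [
        Point(rng.uniform(xmin, xmax), rng.uniform(ymin, ymax))
        for _ in range(n_pts)
    ]
    return segments, pts


def _extract_segments(dem, stream, down, strahler, inflows, order_by_z):
    """Split the stream-cell tree into polylines between junctions."""
    ncols = dem.shape[1]

    def xy(i):
        return tuple(np.asarray(dem.xy(i // ncols, i % ncols), dtype=float))

    is_junction = np.zeros(stream.shape, dtype=bool)
    for i, ups in inflows.items():
        if len(ups) >= 2:
            is_junction[i] = True
    heads = [
        int(i)
        for i in order_by_z
        if stream[i] and not inflows.get(int(i))
    ]
    starts = heads + [int(i) for i in np.flatnonzero(is_junction)]
    segments: list[StreamSegment] = []
    for s in starts:
        coords = [xy(s)]
        i = s
        while True:
            d = int(down[i])
            if d < 0 or not stream[d]:
                break
            coords.append(xy(d))
            i = d
            if is_junction[d]:
                break
        segments.append(StreamSegment(coords=coords, order=int(strahler[s])))
    return segments


def stream_mask(segments: Sequence[StreamSegment], grid: Raster) -> np.ndarray:
    """Rasterize stream segments onto a grid (cells whose centre is on a
    segment vertex or within half a cell of the polyline)."""
    from .raster import rasterize_geometries

    return rasterize_geometries([s.geometry for s in segments], grid)


# ------------------------------------------------------------ barriers

def generate_barriers(
    cfg: LandscapeConfig,
    n_roads: int = 2,
    n_urban: int = 3,
    urban_radius_cells: float = 4.0,
    max_tries: int = 200,
) -> tuple[list[LineString], list[Polygon]]:
    """Road polylines crossing the grid and disjoint urban polygons.

    Roads span the full extent at random angles; urban patches are
    disjoint discs placed by rejection sampling.
    """
    rng = np.random.default_rng(cfg.seed + 4_000)
    grid = cfg.blank_grid()
    xmin, ymin, xmax, ymax = grid.bounds
    roads: list[LineString] = []
    for k in range(n_roads):
        if k % 2 == 0:  # west-east road
            y0, y1 = rng.uniform(ymin, ymax, size=2)
            roads.append(LineString([(xmin, y0), (xmax, y1)]))
        else:  # south-north road
            x0, x1 = rng.uniform(xmin, xmax, size=2)
            roads.append(LineString([(x0, ymin), (x1, ymax)]))
    urban: list[Polygon] = []
    radius = urban_radius_cells * cfg.cell_size
    tries = 0
    while len(urban) < n_urban and tries < max_tries:
        tries += 1
        cx = rng.uniform(xmin + radius, xmax - radius)
        cy = rng.uniform(ymin + radius, ymax - radius)
        patch = Point(cx, cy).buffer(radius, quad_segs=8)
        if all(not patch.intersects(u) for u in urban):
            urban.append(patch)
    if len(urban) < n_urban:
        raise ValueError(
            f"could not place {n_urban} disjoint urban patches "
            f"(placed {len(urban)} in {max_tries} tries)"
        )
    return roads, urban


# ------------------------------------------------------ virtual species

def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def make_virtual_species(
    predictors: RasterStack,
    name: str = "virtualis",
    n_occurrences: int = 128,
    kind: str = "full",
    climate_vars: tuple[str, str] = ("clim_1", "clim_2"),
    water_decay: float = 800.0,
    habitat_bonus: Mapping[int, float] | None = None,
) -> VirtualSpecies:
    """Define a virtual species over a predictor stack.

    ``kind="climate"`` gives a pure logistic function of two climate
    variables (the appropriate truth when only climatic predictors are
    modelled); ``kind="full"`` multiplies in an exponential
    distance-to-water decay (scale ``water_decay`` map units, layer
    ``dist_water``) and a habitat-class bonus (layer ``habitat``), so
    every predictor family used by the fine-scale overlay matters.
    """
    v1, v2 = climate_vars
    if habitat_bonus is None:
        habitat_bonus = {0: 0.4, 1: 0.7, 2: 1.0, 3: 0.6}

    def fn(df: pd.DataFrame) -> np.ndarray:
        s = _logistic(0.5 + 1.8 * df[v1].to_numpy() - 1.2 * df[v2].to_numpy() ** 2)
        if kind == "full":
            s = s * np.exp(-df["dist_water"].to_numpy() / water_decay)
            bonus = np.vectorize(lambda c: habitat_bonus.get(int(c), 0.5))(
                df["habitat"].to_numpy()
            )
            s = s * bonus
        return np.clip(s, 0.0, 1.0)

    table = predictors.table()
    suit = fn(table).reshape(predictors.grid.shape)
    truth = predictors.grid.with_values(suit)
    return VirtualSpecies(
        name=name, suitability_fn=fn, true_suitability=truth, n_occurrences=n_occurrences
    )


def sample_occurrences(vs: VirtualSpecies, seed: int) -> pd.DataFrame:
    """Occurrence points drawn with inclusion probability proportional to
    the true suitability, without replacement at the cell level.

    Points sit at cell centres (one per cell), mirroring an
    already-thinned occurrence dataset.  Returns a DataFrame with
    columns ``x, y, species``.
    """
    truth = vs.true_suitability
    suit = truth.masked().ravel()
    suit = np.where(np.isfinite(suit), suit, 0.0)
    total = suit.sum()
    if total <= 0:
        raise ValueError("all-zero suitability: cannot sample occurrences")
    n_pos = int((suit > 0).sum())
    if n_pos < vs.n_occurrences:
        raise ValueError(
            f"only {n_pos} cells with positive suitability for "
            f"{vs.n_occurrences} requested occurrences"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(suit.size, size=vs.n_occurrences, replace=False, p=suit / total)
    ncols = truth.shape[1]
    x, y = truth.xy(idx // ncols, idx % ncols)
    return pd.DataFrame({"x": x, "y": y, "species": vs.name})


# ------------------------------------------------------------- bundles

@dataclass
class Landscape:
    """A fully generated synthetic landscape."""

    cfg: LandscapeConfig
    climate: dict[str, RasterStack]
    dem: Raster
    slope: Raster
    aspect: Raster
    habitat: Raster
    streams: list[StreamSegment]
    water_points: list[Point]
    dist_stream: Raster
    dist_water: Raster
    roads: list[LineString]
    urban: list[Polygon]

    def predictors(self, scenario: str = "present") -> RasterStack:
        """Full predictor stack (climate + terrain + habitat + distances)."""
        layers = {n: self.climate[scenario][n] for n in self.climate[scenario].names}
        layers.update(
            slope=self.slope,
            aspect=self.aspect,
            habitat=self.habitat,
            dist_stream=self.dist_stream,
            dist_water=self.dist_water,
        )
        return RasterStack(layers)


def generate_landscape(
    cfg: LandscapeConfig,
    max_strahler_order: int = 3,
    n_roads: int = 2,
    n_urban: int = 3,
) -> Landscape:
    """Generate the complete synthetic landscape bundle.

    Distance-to-stream uses only segments with Strahler order up to
    ``max_strahler_order`` (small tributaries; high-order rivers are
    excluded as unusable habitat).
    """
    from .raster import filter_streams, rasterize_geometries, slope_aspect

    climate = generate_climate_stack(cfg)
    dem = generate_dem(cfg)
    slope, aspect = slope_aspect(dem)
    habitat = generate_habitat(cfg)
    streams, water_points = generate_hydrology(cfg, dem)
    small = filter_streams(streams, max_order=max_strahler_order)
    grid = cfg.blank_grid()
    smask = stream_mask(small, grid) if small else stream_mask(streams, grid)
    dist_stream = euclidean_distance(smask, grid)
    wmask = rasterize_geometries(water_points, grid)
    dist_water = euclidean_distance(wmask, grid)
    roads, urban = generate_barriers(cfg, n_roads=n_roads, n_urban=n_urban)
    return Landscape(
        cfg=cfg,
        climate=climate,
        dem=dem,
        slope=slope,
        aspect=aspect,
        habitat=habitat,
        streams=streams,
        water_points=water_points,
        dist_stream=dist_stream,
        dist_water=dist_water,
        roads=roads,
        urban=urban,
    )
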