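"""Resistance surfaces and circuit-theory connectivity on raster grids.

Habitat suitability h in [0, 1] maps to movement resistance through the
negative-exponential transform of Keeley et al.'s family::

    R(h) = 100 - 99 * (1 - exp(-c h)) / (1 - exp(-c))

so R(0) = 100, R(1) = 1, strictly decreasing, with curvature c
(default 4: resistance drops quickly as suitability rises).  Road and
urban barriers are burnt into the suitability layer as zero-suitability
(maximum-resistance) cells beforehand.

The landscape is then an electrical network: one node per valid cell,
edges between 8-neighbours with conductance 1 / mean(R_i, R_j)
(diagonal edges additionally divided by sqrt(2) for the longer span).
In pairwise mode, 1 A is injected at one focal node and withdrawn at
another for every unordered pair of focal nodes (occurrences snapped to
cells); the cumulative per-cell current over all pairs is the corridor
map — the expected net movement density of a random walker.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse import csgraph
from scipy.sparse.linalg import splu

from .raster import Raster, rasterize_geometries

__all__ = [
    "ResistanceSurface",
    "GridGraph",
    "NodeSet",
    "CurrentMap",
    "normalize_suitability",
    "burn_barriers",
    "suitability_to_resistance",
    "build_grid_graph",
    "snap_nodes",
    "solve_pairwise",
    "effective_resistance",
]

RESISTANCE_MIN = 1.0
RESISTANCE_MAX = 100.0


# ------------------------------------------------------------ surfaces

def normalize_suitability(sdm: Raster) -> Raster:
    """Min-max rescale of a suitability raster to [0, 1]."""
    v = sdm.masked()
    lo = np.nanmin(v)
    hi = np.nanmax(v)
    if not np.isfinite(lo) or hi <= lo:
        raise ValueError("constant (or empty) raster cannot be normalized")
    return sdm.with_values((v - lo) / (hi - lo), nodata=None)


def burn_barriers(suitability: Raster, roads=(), urban=()) -> Raster:
    """Set suitability to 0 (maximum resistance) on cells intersecting
    road polylines or urban polygons; other cells unchanged."""
    geoms = list(roads) + list(urban)
    if not geoms:
        return suitability
    mask = rasterize_geometries(geoms, suitability)
    v = suitability.masked().copy()
    v[mask] = 0.0
    return suitability.with_values(v, nodata=None)


@dataclass
class ResistanceSurface:
    """Per-cell movement resistance in [1, 100]."""

    raster: Raster
    c: float
    barrier_mask: np.ndarray | None = None

    @property
    def values(self) -> np.ndarray:
        return self.raster.values


def suitability_to_resistance(h: Raster, c: float = 4.0) -> ResistanceSurface:
    """Negative-exponential suitability-to-resistance transform
    (R(0)=100, R(1)=1, strictly decreasing; curvature ``c``)."""
    if c <= 0:
        raise ValueError("c must be positive")
    v = h.masked()
    finite = v[np.isfinite(v)]
    if finite.size and (finite.min() < 0 or finite.max() > 1):
        raise ValueError("suitability must lie in [0, 1]; normalize first")
    R = RESISTANCE_MAX - (RESISTANCE_MAX - RESISTANCE_MIN) * (
        1 - np.exp(-c * v)
    ) / (1 - np.exp(-c))
    return ResistanceSurface(raster=h.with_values(R, nodata=None), c=c)


# ---------------------------------------------------------- grid graph

@dataclass
class GridGraph:
    """Weighted graph over the valid cells of a resistance raster."""

    grid: Raster
    node_of_cell: np.ndarray  # (rows, cols) -> node id or -1
    cells: np.ndarray  # node id -> flat cell index
    edges_i: np.ndarray
    edges_j: np.ndarray
    conductance: np.ndarray

    @property
    def n_nodes(self) -> int:
        return len(self.cells)

    def laplacian(self) -> sparse.csr_matrix:
        n = self.n_nodes
        i, j, g = self.edges_i, self.edges_j, self.conductance
        W = sparse.coo_matrix(
            (np.r_[g, g], (np.r_[i, j], np.r_[j, i])), shape=(n, n)
        ).tocsr()
        D = sparse.diags(np.asarray(W.sum(axis=1)).ravel())
        return (D - W).tocsc()

    def components(self) -> np.ndarray:
        n = self.n_nodes
        A = sparse.coo_matrix(
            (np.ones(len(self.edges_i) * 2),
             (np.r_[self.edges_i, self.edges_j], np.r_[self.edges_j, self.edges_i])),
            shape=(n, n),
        )
        _, labels = csgraph.connected_components(A, directed=False)
        return labels


_NEIGH_4 = [(0, 1), (1, 0)]
_NEIGH_8 = [(0, 1), (1, 0), (1, 1), (1, -1)]


def build_grid_graph(res: ResistanceSurface | Raster, neighborhood: int = 8) -> GridGraph:
    """Grid graph with edge conductance 1 / mean(R_i, R_j); diagonal
    conductances divided by sqrt(2).  Nodata cells are excluded."""
    raster = res.raster if isinstance(res, ResistanceSurface) else res
    if neighborhood not in (4, 8):
        raise ValueError("neighborhood must be 4 or 8")
    R = raster.masked()
    valid = np.isfinite(R)
    if valid.sum() < 2:
        raise ValueError("need at least two valid cells")
    nrows, ncols = R.shape
    node_of_cell = np.full(R.shape, -1, dtype=np.int64)
    cells = np.flatnonzero(valid.ravel())
    node_of_cell.ravel()[cells] = np.arange(len(cells))
    offsets = _NEIGH_4 if neighborhood == 4 else _NEIGH_8
    ei, ej, g = [], [], []
    for dr, dc in offsets:
        r0 = slice(max(-dr, 0), nrows - max(dr, 0))
        r1 = slice(max(dr, 0), nrows - max(-dr, 0))
        c0 = slice(max(-dc, 0), ncols - max(dc, 0))
        c1 = slice(max(dc, 0), ncols - max(-dc, 0))
        a = node_of_cell[r0, c0]
        b = node_of_cell[r1, c1]
        Ra = R[r0, c0]
        Rb = R[r1, c1]
        ok = (a >= 0) & (b >= 0)
        cond = 1.0 / ((Ra[ok] + Rb[ok]) / 2.0)
        if dr != 0 and dc != 0:
            cond = cond / np.sqrt(2.0)
        ei.append(a[ok])
        ej.append(b[ok])
        g.append(cond)
    return GridGraph(
        grid=raster,
        node_of_cell=node_of_cell,
        cells=cells,
        edges_i=np.concatenate(ei),
        edges_j=np.concatenate(ej),
        conductance=np.concatenate(g),
    )


# --------------------------------------------------------------- nodes

@dataclass
class NodeSet:
    """Focal nodes: occurrence points snapped to grid cells, deduplicated."""

    node_ids: np.ndarray

    def __len__(self) -> int:
        return len(self.node_ids)


def snap_nodes(graph: GridGraph, occurrences: pd.DataFrame) -> NodeSet:
    """Snap occurrence (x, y) points to graph nodes; coincident points
    collapse; points on nodata cells raise."""
    grid = graph.grid
    row, col = grid.index(
        occurrences["x"].to_numpy(dtype=float), occurrences["y"].to_numpy(dtype=float)
    )
    nrows, ncols = grid.shape
    if (row < 0).any() or (row >= nrows).any() or (col < 0).any() or (col >= ncols).any():
        raise ValueError("occurrence outside the raster extent")
    ids = graph.node_of_cell[row, col]
    if (ids < 0).any():
        bad = occurrences.loc[ids < 0, ["x", "y"]]
        raise ValueError(f"occurrences on nodata cells:\n{bad}")
    return NodeSet(node_ids=np.unique(ids))


# ------------------------------------------------------------- solving

@dataclass
class CurrentMap:
    """Cumulative pairwise current (amperes; 1 A injected per pair)."""

    raster: Raster
    n_pairs: int
    nodes: NodeSet

    def per_pair_mean(self) -> Raster:
        """Cumulative current divided by the number of pairs (needed to
        compare connectivity across node sets of different size)."""
        return self.raster.with_values(self.raster.values / self.n_pairs)


def _select_pairs(node_ids: np.ndarray, max_pairs: int | None):
    pairs = list(combinations(range(len(node_ids)), 2))
    if max_pairs is None or len(pairs) <= max_pairs:
        return pairs
    # deterministic even-spaced subsample of the ordered pair list
    idx = np.linspace(0, len(pairs) - 1, max_pairs).round().astype(int)
    return [pairs[k] for k in np.unique(idx)]


def solve_pairwise(
    graph: GridGraph,
    nodes: NodeSet,
    max_pairs: int | None = None,
) -> CurrentMap:
    """Pairwise-mode current map.

    For each unordered focal pair (s, t), 1 A is injected at s and
    withdrawn at the grounded t; per-cell current is half the sum of the
    absolute currents on incident edges (the full 1 A at the focal
    cells); maps are summed over pairs.  All focal nodes must share one
    connected component.
    """
    if len(nodes) < 2:
        raise ValueError("need at least two focal nodes")
    labels = graph.components()
    focal_labels = labels[nodes.node_ids]
    if len(np.unique(focal_labels)) > 1:
        groups = {
            int(c): nodes.node_ids[focal_labels == c].tolist()
            for c in np.unique(focal_labels)
        }
        raise ValueError(f"focal nodes span disconnected components: {groups}")
    L = graph.laplacian()
    ground = int(nodes.node_ids[0])
    keep = np.arange(graph.n_nodes) != ground
    L_red = L[keep][:, keep].tocsc()
    lu = splu(L_red)
    red_index = np.cumsum(keep) - 1  # node id -> reduced index

    # potentials for unit injection at each focal node (ground fixed at 0)
    pots = {}
    for t in nodes.node_ids:
        t = int(t)
        if t == ground:
            pots[t] = np.zeros(graph.n_nodes)
            continue
        e = np.zeros(graph.n_nodes - 1)
        e[red_index[t]] = 1.0
        v = lu.solve(e)
        full = np.zeros(graph.n_nodes)
        full[keep] = v
        pots[t] = full

    pairs = _select_pairs(nodes.node_ids, max_pairs)
    cum = np.zeros(graph.n_nodes)
    ei, ej, g = graph.edges_i, graph.edges_j, graph.conductance
    for a, b in pairs:
        s = int(nodes.node_ids[a])
        t = int(nodes.node_ids[b])
        v = pots[s] - pots[t]
        edge_cur = np.abs(g * (v[ei] - v[ej]))
        node_cur = np.zeros(graph.n_nodes)
        np.add.at(node_cur, ei, edge_cur)
        np.add.at(node_cur, ej, edge_cur)
        node_cur *= 0.5
        node_cur[s] = 1.0
        node_cur[t] = 1.0
        cum += node_cur
    out = np.full(graph.grid.shape, np.nan).ravel()
    out[graph.cells] = cum
    raster = graph.grid.with_values(out.reshape(graph.grid.shape), nodata=None)
    return CurrentMap(raster=raster, n_pairs=len(pairs), nodes=nodes)


def node_potentials(graph: GridGraph, s: int, t: int) -> np.ndarray:
    """Node voltages for 1 A injected at s, withdrawn at grounded t."""
    L = graph.laplacian()
    keep = np.arange(graph.n_nodes) != t
    L_red = L[keep][:, keep].tocsc()
    rhs = np.zeros(graph.n_nodes)
    rhs[s] = 1.0
    v = splu(L_red).solve(rhs[keep])
    full = np.zeros(graph.n_nodes)
    full[keep] = v
    return full


def effective_resistance(graph: GridGraph, s: int, t: int) -> float:
    """Effective resistance between two nodes (ohms): the voltage
    difference under 1 A injection.  Infinite if disconnected."""
    labels = graph.components()
    if labels[s] != labels[t]:
        return float("inf")
    v = node_potentials(graph, s, t)
    return float(v[s] - v[t])
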