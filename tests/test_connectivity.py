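"""Resistance transform and circuit-theory solver: closed forms, dense
pseudoinverse oracle, conservation and monotonicity properties."""

import numpy as np
import pandas as pd
import pytest

from nichecircuit import (
    build_grid_graph,
    burn_barriers,
    effective_resistance,
    normalize_suitability,
    snap_nodes,
    solve_pairwise,
    suitability_to_resistance,
)
from nichecircuit.connectivity import GridGraph, NodeSet, node_potentials

from conftest import make_raster


def graph_from_edges(n, edges):
    """Hand-built graph (node ids, conductances) for closed-form cases."""
    ei, ej, g = zip(*edges)
    return GridGraph(
        grid=make_raster(np.zeros((1, n))),
        node_of_cell=np.arange(n).reshape(1, n),
        cells=np.arange(n),
        edges_i=np.array(ei),
        edges_j=np.array(ej),
        conductance=np.array(g, dtype=float),
    )


class TestNormalizeAndBarriers:
    def test_full_range_identity(self):
        v = np.array([[0.0, 0.25], [0.75, 1.0]])
        out = normalize_suitability(make_raster(v))
        assert np.allclose(out.values, v)

    def test_affine_rescale(self):
        out = normalize_suitability(make_raster(np.array([[10.0, 20.0, 30.0]])))
        assert np.allclose(out.values, [[0.0, 0.5, 1.0]])

    def test_constant_raises(self):
        with pytest.raises(ValueError, match="constant"):
            normalize_suitability(make_raster(np.full((3, 3), 0.5)))

    def test_empty_barriers_identity(self, rng):
        r = make_raster(rng.random((5, 5)))
        out = burn_barriers(r)
        assert np.allclose(out.values, r.values)

    def test_barrier_cell_zeroed(self):
        from shapely.geometry import Point

        r = make_raster(np.ones((5, 5)), cell=100.0)
        urban = [Point(250.0, 250.0).buffer(10.0)]
        out = burn_barriers(r, urban=urban)
        assert out.values[2, 2] == 0.0
        assert out.values[0, 0] == 1.0

    def test_road_zeroes_full_row(self):
        from shapely.geometry import LineString

        r = make_raster(np.ones((5, 5)), cell=100.0)
        road = [LineString([(0.0, 250.0), (500.0, 250.0)])]
        out = burn_barriers(r, roads=road)
        assert np.allclose(out.values[2], 0.0)
        assert np.allclose(out.values[[0, 1, 3, 4]], 1.0)


class TestKeeleyTransform:
    def test_endpoints(self):
        r = suitability_to_resistance(make_raster(np.array([[0.0, 1.0]])), c=4.0)
        assert r.values[0, 0] == pytest.approx(100.0)
        assert r.values[0, 1] == pytest.approx(1.0)

    def test_midpoint_closed_form(self):
        r = suitability_to_resistance(make_raster(np.array([[0.5]])), c=4.0)
        expected = 100 - 99 * (1 - np.exp(-2.0)) / (1 - np.exp(-4.0))
        assert r.values[0, 0] == pytest.approx(expected, abs=1e-9)

    def test_strictly_decreasing_on_fine_grid(self):
        h = np.linspace(0.0, 1.0, 1001).reshape(1, -1)
        r = suitability_to_resistance(make_raster(h), c=4.0)
        assert np.all(np.diff(r.values[0]) < 0)
        assert r.values.min() >= 1.0 and r.values.max() <= 100.0

    def test_out_of_range_suitability_raises(self):
        with pytest.raises(ValueError, match="0, 1"):
            suitability_to_resistance(make_raster(np.array([[1.5]])))


class TestGridGraph:
    def test_rook_conductances(self):
        g = build_grid_graph(make_raster(np.array([[1.0, 1.0]])))
        assert g.conductance[0] == pytest.approx(1.0)
        g2 = build_grid_graph(make_raster(np.array([[2.0, 4.0]])))
        assert g2.conductance[0] == pytest.approx(1 / 3)

    def test_diagonal_scaling(self):
        R = np.array([[2.0, np.nan], [np.nan, 4.0]])
        g = build_grid_graph(make_raster(R))
        assert len(g.conductance) == 1
        assert g.conductance[0] == pytest.approx(1 / (3 * np.sqrt(2)))

    def test_nodata_cells_excluded(self):
        R = np.array([[1.0, np.nan, 1.0]])
        g = build_grid_graph(make_raster(R))
        assert g.n_nodes == 2 and len(g.conductance) == 0


class TestEffectiveResistance:
    def test_single_edge(self):
        g = graph_from_edges(2, [(0, 1, 2.0)])
        assert effective_resistance(g, 0, 1) == pytest.approx(0.5)

    def test_two_parallel_two_edge_unit_paths(self):
        # square: 0-1-2 and 0-3-2, all unit resistors -> R_eff(0,2) = 1
        g = graph_from_edges(4, [(0, 1, 1.0), (1, 2, 1.0), (0, 3, 1.0), (3, 2, 1.0)])
        assert effective_resistance(g, 0, 2) == pytest.approx(1.0)

    def test_triangle_of_unit_resistors(self):
        g = graph_from_edges(3, [(0, 1, 1.0), (1, 2, 1.0), (0, 2, 1.0)])
        for s, t in [(0, 1), (1, 2), (0, 2)]:
            assert effective_resistance(g, s, t) == pytest.approx(2 / 3)

    def test_disconnected_infinite(self):
        g = graph_from_edges(4, [(0, 1, 1.0), (2, 3, 1.0)])
        assert effective_resistance(g, 0, 3) == np.inf

    def test_rayleigh_monotonicity(self):
        """Raising any cell's resistance never lowers effective resistance."""
        rng = np.random.default_rng(5)
        R = rng.uniform(1, 50, size=(6, 6))
        g = build_grid_graph(make_raster(R))
        base = effective_resistance(g, 0, g.n_nodes - 1)
        for _ in range(5):
            r, c = rng.integers(0, 6, size=2)
            R2 = R.copy()
            R2[r, c] *= 3.0
            g2 = build_grid_graph(make_raster(R2))
            assert effective_resistance(g2, 0, g2.n_nodes - 1) >= base - 1e-10

    def test_scale_property(self):
        rng = np.random.default_rng(6)
        R = rng.uniform(1, 20, size=(5, 5))
        g1 = build_grid_graph(make_raster(R))
        g2 = build_grid_graph(make_raster(7.0 * R))
        assert effective_resistance(g2, 0, 24) == pytest.approx(
            7.0 * effective_resistance(g1, 0, 24)
        )


def dense_oracle_potentials(graph, s, t):
    """Voltages via the dense Laplacian pseudoinverse."""
    n = graph.n_nodes
    L = np.zeros((n, n))
    for i, j, g in zip(graph.edges_i, graph.edges_j, graph.conductance):
        L[i, i] += g
        L[j, j] += g
        L[i, j] -= g
        L[j, i] -= g
    rhs = np.zeros(n)
    rhs[s] = 1.0
    rhs[t] = -1.0
    v = np.linalg.pinv(L, hermitian=True) @ rhs
    return v - v[t]


class TestSolvePairwise:
    def test_series_circuit_middle_current(self):
        g = build_grid_graph(make_raster(np.ones((1, 3))))
        nodes = NodeSet(node_ids=np.array([0, 2]))
        cur = solve_pairwise(g, nodes)
        assert cur.raster.values[0, 1] == pytest.approx(1.0)
        assert cur.raster.values[0, 0] == pytest.approx(1.0)
        assert cur.n_pairs == 1

    def test_mirror_symmetry(self):
        # symmetric two-corridor landscape; focal nodes on the symmetry axis
        R = np.ones((5, 5))
        R[2, 1:4] = 50.0  # central obstacle splits flow into two corridors
        g = build_grid_graph(make_raster(R))
        r, c = np.nonzero(np.isfinite(R))
        ids = g.node_of_cell
        nodes = NodeSet(node_ids=np.array([ids[2, 0], ids[2, 4]]))
        cur = solve_pairwise(g, nodes)
        assert np.allclose(cur.raster.values, cur.raster.values[::-1], atol=1e-10)

    def test_matches_dense_oracle_on_random_grids(self):
        for seed in range(6):
            rng = np.random.default_rng(seed)
            shape = rng.integers(3, 9, size=2)
            R = rng.uniform(1, 100, size=shape)
            g = build_grid_graph(make_raster(R))
            ids = rng.choice(g.n_nodes, size=min(4, g.n_nodes), replace=False)
            for s, t in [(ids[0], ids[1]), (ids[-2], ids[-1])]:
                if s == t:
                    continue
                v = node_potentials(g, int(s), int(t))
                vo = dense_oracle_potentials(g, int(s), int(t))
                assert np.allclose(v, vo, atol=1e-8)

    def test_kirchhoff_conservation(self):
        rng = np.random.default_rng(9)
        R = rng.uniform(1, 100, size=(7, 7))
        g = build_grid_graph(make_raster(R))
        s, t = 3, 44
        v = node_potentials(g, s, t)
        net = np.zeros(g.n_nodes)
        flow = g.conductance * (v[g.edges_i] - v[g.edges_j])
        np.add.at(net, g.edges_i, -flow)
        np.add.at(net, g.edges_j, flow)
        assert net[s] == pytest.approx(-1.0, abs=1e-8)
        assert net[t] == pytest.approx(1.0, abs=1e-8)
        mask = np.ones(g.n_nodes, dtype=bool)
        mask[[s, t]] = False
        assert np.abs(net[mask]).max() < 1e-8

    def test_current_map_invariant_to_resistance_scale(self):
        rng = np.random.default_rng(10)
        R = rng.uniform(1, 30, size=(6, 6))
        nodes = NodeSet(node_ids=np.array([0, 17, 35]))
        c1 = solve_pairwise(build_grid_graph(make_raster(R)), nodes)
        c2 = solve_pairwise(build_grid_graph(make_raster(5.0 * R)), nodes)
        assert np.allclose(c1.raster.values, c2.raster.values, atol=1e-9)

    def test_disconnected_nodes_error_names_components(self):
        R = np.ones((3, 3))
        R[:, 1] = np.nan
        g = build_grid_graph(make_raster(R))
        nodes = NodeSet(node_ids=np.array([0, g.n_nodes - 1]))
        with pytest.raises(ValueError, match="components"):
            solve_pairwise(g, nodes)

    def test_cumulative_is_sum_over_pairs(self):
        rng = np.random.default_rng(11)
        R = rng.uniform(1, 10, size=(4, 4))
        g = build_grid_graph(make_raster(R))
        all_nodes = NodeSet(node_ids=np.array([0, 5, 15]))
        cum = solve_pairwise(g, all_nodes)
        parts = [
            solve_pairwise(g, NodeSet(node_ids=np.array(p)))
            for p in ([0, 5], [0, 15], [5, 15])
        ]
        total = sum(p.raster.values for p in parts)
        assert np.allclose(cum.raster.values, total, atol=1e-9)
        assert cum.n_pairs == 3
        assert np.allclose(cum.per_pair_mean().values, cum.raster.values / 3)

    def test_max_pairs_subsampling_deterministic(self):
        rng = np.random.default_rng(12)
        R = rng.uniform(1, 10, size=(5, 5))
        g = build_grid_graph(make_raster(R))
        nodes = NodeSet(node_ids=np.array([0, 6, 12, 18, 24]))
        a = solve_pairwise(g, nodes, max_pairs=4)
        b = solve_pairwise(g, nodes, max_pairs=4)
        assert a.n_pairs == 4
        assert np.array_equal(a.raster.values, b.raster.values)


class TestSnapNodes:
    def test_snap_and_dedupe(self):
        g = build_grid_graph(make_raster(np.ones((4, 4)), cell=100.0))
        occ = pd.DataFrame(
            {"x": [50.0, 60.0, 250.0], "y": [350.0, 340.0, 150.0]}
        )
        nodes = snap_nodes(g, occ)
        assert len(nodes) == 2  # first two share a cell

    def test_nodata_cell_rejected(self):
        R = np.ones((3, 3))
        R[0, 0] = np.nan
        g = build_grid_graph(make_raster(R, cell=100.0))
        occ = pd.DataFrame({"x": [50.0], "y": [250.0]})
        with pytest.raises(ValueError, match="nodata"):
            snap_nodes(g, occ)
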