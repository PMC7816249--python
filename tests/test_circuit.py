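import numpy as np
import pytest

from circuitmig.circuit import (
    CircuitProblem,
    DisconnectedTerminalsError,
    build_graph,
    individual_current_map,
    snap_to_valid,
    solve,
)
from circuitmig.raster import RasterGrid


def dense_solve_oracle(resistance: RasterGrid, src_rc, gnd_rc):
    """Independent dense Laplacian solve built edge by edge with loops."""
    nr, nc = resistance.shape
    idx = {}
    for r in range(nr):
        for c in range(nc):
            if np.isfinite(resistance.data[r, c]):
                idx[(r, c)] = len(idx)
    n = len(idx)
    L = np.zeros((n, n))
    for (r, c), i in idx.items():
        for dr, dc in [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]:
            j = idx.get((r + dr, c + dc))
            if j is None:
                continue
            dist = np.hypot(dr, dc)
            g = 2.0 / (dist * (resistance.data[r, c] + resistance.data[r + dr, c + dc]))
            L[i, j] -= g
            L[i, i] += g
    s, t = idx[src_rc], idx[gnd_rc]
    keep = [i for i in range(n) if i != t]
    b = np.zeros(n)
    b[s] = 1.0
    v = np.zeros(n)
    v[keep] = np.linalg.solve(L[np.ix_(keep, keep)], b[keep])
    return v[s]


class TestBuildGraph:
    def test_full_grid_edge_count(self):
        for m, n in [(3, 3), (2, 5), (4, 4)]:
            g = build_graph(RasterGrid(np.ones((m, n))))
            expected = m * (n - 1) + n * (m - 1) + 2 * (m - 1) * (n - 1)
            assert g.n_edges == expected

    def test_uniform_conductances(self):
        g = build_graph(RasterGrid(np.ones((3, 3))))
        assert set(np.round(g.conductances, 6)) == {
            1.0, round(1 / np.sqrt(2), 6),
        }

    def test_nodata_center_removes_eight_edges(self):
        full = build_graph(RasterGrid(np.ones((3, 3)))).n_edges
        data = np.ones((3, 3))
        data[1, 1] = np.nan
        holed = build_graph(RasterGrid(data)).n_edges
        assert full - holed == 8

    def test_nonpositive_resistance_rejected(self):
        with pytest.raises(ValueError):
            build_graph(RasterGrid(np.zeros((3, 3))))


class TestSolve:
    def test_series_circuit_1x3(self):
        sol = solve(CircuitProblem(RasterGrid(np.ones((1, 3))), (0, 0), (0, 2)))
        assert sol.effective_resistance == pytest.approx(2.0, abs=1e-10)
        assert sol.current_map.data[0, 1] == pytest.approx(1.0, abs=1e-10)

    def test_2x2_diagonal_pair(self):
        sol = solve(CircuitProblem(RasterGrid(np.ones((2, 2))), (0, 0), (1, 1)))
        assert sol.effective_resistance == pytest.approx(2 - np.sqrt(2), abs=1e-10)
        # off-terminal nodes sit at equal voltage; no current crosses between them
        off = [i for i in range(4) if i not in (sol.source_node, sol.ground_node)]
        assert sol.voltages[off[0]] == pytest.approx(sol.voltages[off[1]], abs=1e-12)

    def test_kirchhoff_residual(self, rng):
        res = RasterGrid(rng.uniform(0.5, 10, (15, 15)))
        sol = solve(CircuitProblem(res, (0, 0), (14, 14)))
        assert sol.kirchhoff_residual < 1e-6

    @pytest.mark.parametrize("trial", range(5))
    def test_matches_dense_oracle(self, trial):
        rng = np.random.default_rng(trial)
        shape = rng.integers(4, 13, 2)
        res = RasterGrid(rng.uniform(0.2, 50, shape))
        gnd = (int(shape[0] - 1), int(shape[1] - 1))
        sol = solve(CircuitProblem(res, (0, 0), gnd))
        oracle = dense_solve_oracle(res, (0, 0), gnd)
        assert sol.effective_resistance == pytest.approx(oracle, rel=1e-8)

    def test_reciprocity(self, rng):
        res = RasterGrid(rng.uniform(0.5, 5, (8, 8)))
        a = solve(CircuitProblem(res, (0, 0), (7, 7)))
        b = solve(CircuitProblem(res, (7, 7), (0, 0)))
        assert a.effective_resistance == pytest.approx(b.effective_resistance, rel=1e-10)

    def test_rayleigh_monotonicity(self, rng):
        data = rng.uniform(1, 10, (10, 10))
        base = solve(CircuitProblem(RasterGrid(data), (0, 0), (9, 9))).effective_resistance
        for _ in range(5):
            bumped = data.copy()
            r, c = rng.integers(0, 10, 2)
            bumped[r, c] *= 10
            up = solve(
                CircuitProblem(RasterGrid(bumped), (0, 0), (9, 9))
            ).effective_resistance
            assert up >= base - 1e-10

    def test_scale_invariance_of_current_map(self, rng):
        data = rng.uniform(0.5, 8, (9, 9))
        a = solve(CircuitProblem(RasterGrid(data), (0, 0), (8, 8)))
        b = solve(CircuitProblem(RasterGrid(2.0 * data), (0, 0), (8, 8)))
        np.testing.assert_allclose(
            a.current_map.data, b.current_map.data, rtol=1e-8
        )
        assert b.effective_resistance == pytest.approx(
            2 * a.effective_resistance, rel=1e-10
        )

    def test_disconnected_terminals_error_names_components(self):
        data = np.ones((3, 5))
        data[:, 2] = np.nan  # wall splits the grid
        with pytest.raises(DisconnectedTerminalsError, match="component"):
            solve(CircuitProblem(RasterGrid(data), (0, 0), (0, 4)))

    def test_mirror_symmetry(self):
        res = RasterGrid(np.ones((5, 7)))
        sol = solve(CircuitProblem(res, (2, 1), (2, 5)))
        cm = sol.current_map.data
        np.testing.assert_allclose(cm, cm[::-1, :], atol=1e-9)  # up-down mirror
        np.testing.assert_allclose(cm, cm[:, ::-1], atol=1e-9)  # swap terminals


class TestSnapAndIndividual:
    def test_no_snap_at_valid_center(self, uniform_grid):
        x, y = uniform_grid.rowcol_to_xy(3, 4)
        assert snap_to_valid(uniform_grid, x, y) == (3, 4)

    def test_snap_to_nearest_valid(self):
        data = np.ones((5, 5))
        data[2, 2] = np.nan
        g = RasterGrid(data)
        x, y = g.rowcol_to_xy(2, 2)
        r, c = snap_to_valid(g, x, y)
        assert (r, c) != (2, 2) and abs(r - 2) <= 1 and abs(c - 2) <= 1

    def test_snap_failure(self):
        data = np.full((13, 13), np.nan)
        data[0, 0] = 1.0
        g = RasterGrid(data)
        x, y = g.rowcol_to_xy(12, 12)
        from circuitmig.circuit import SnapError

        with pytest.raises(SnapError):
            snap_to_valid(g, x, y, max_radius_cells=5)

    def test_individual_map_halved_resistance_identical(self, rng):
        data = rng.uniform(1, 20, (12, 12))
        g1 = RasterGrid(data)
        g2 = RasterGrid(data / 2.0)
        p1, p2 = g1.rowcol_to_xy(1, 1), g1.rowcol_to_xy(10, 10)
        a = individual_current_map(g1, p1, p2)
        b = individual_current_map(g2, p1, p2)
        np.testing.assert_allclose(a.current_map.data, b.current_map.data, rtol=1e-8)
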