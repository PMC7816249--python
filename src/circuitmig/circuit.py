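"""Raster circuit-theory engine.

Each valid raster cell is a node of an electrical network; neighbouring
cells (8-neighbourhood) are joined by resistors formed from the two cells'
half-cell resistances in series, ``R_edge = (r_i + r_j) / 2``, with diagonal
edges scaled by the centre-to-centre distance sqrt(2).  Injecting one unit
of current at a migration's start cell (source) and grounding its end cell
solves the graph Laplacian system ``L v = b``; the current through each
cell is then proportional to the expected number of passages of a random
walker travelling source to ground, which is what makes current density a
connectivity map.

The solver is a sparse Cholesky-type direct factorisation of the grounded
(reduced) Laplacian, which is symmetric positive definite; the Kirchhoff
residual of every solution is checked against the requested tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import splu

from .raster import RasterGrid

__all__ = [
    "ConductanceGraph",
    "CircuitProblem",
    "CircuitSolution",
    "DisconnectedTerminalsError",
    "SnapError",
    "build_graph",
    "solve",
    "snap_to_valid",
    "individual_current_map",
]

# 8-neighbour offsets; only "forward" half listed so each edge appears once
_FORWARD = [(0, 1, 1.0), (1, 0, 1.0), (1, 1, np.sqrt(2.0)), (1, -1, np.sqrt(2.0))]


class DisconnectedTerminalsError(RuntimeError):
    """Source and ground fall in different connected components."""


class SnapError(RuntimeError):
    """No valid cell within the snap radius of a terminal coordinate."""


@dataclass
class ConductanceGraph:
    """Sparse conductance network over the valid cells of a resistance grid."""

    grid: RasterGrid
    node_index: np.ndarray  # (nrows, ncols) int, -1 where nodata
    nodes_rc: np.ndarray  # (n_nodes, 2) row/col per node
    edges: np.ndarray  # (n_edges, 2) node index pairs
    conductances: np.ndarray  # (n_edges,)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes_rc)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def laplacian(self) -> sparse.csc_matrix:
        i, j = self.edges[:, 0], self.edges[:, 1]
        g = self.conductances
        n = self.n_nodes
        rows = np.concatenate([i, j, i, j])
        cols = np.concatenate([j, i, i, j])
        vals = np.concatenate([-g, -g, g, g])
        return sparse.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsc()


def build_graph(resistance: RasterGrid) -> ConductanceGraph:
    """Build the 8-neighbour conductance graph of a resistance surface.

    Orthogonal edges get conductance ``2 / (r_i + r_j)``; diagonal edges
    ``2 / (sqrt(2) * (r_i + r_j))``.  Nodata cells are excluded together
    with all incident edges.
    """
    r = resistance.data
    ok = resistance.valid
    if not ok.any():
        raise ValueError("resistance raster contains no valid cells")
    if (r[ok] <= 0).any():
        raise ValueError("resistance must be strictly positive on valid cells")

    node_index = np.full(resistance.shape, -1, dtype=int)
    nodes_rc = np.argwhere(ok)
    node_index[ok] = np.arange(len(nodes_rc))

    edge_i, edge_j, cond = [], [], []
    nrows, ncols = resistance.shape
    for dr, dc, dist in _FORWARD:
        # pair cell a = (row, col) with cell b = (row + dr, col + dc)
        a_rows = slice(0, nrows - dr)
        b_rows = slice(dr, nrows)
        a_cols = slice(max(0, -dc), ncols - max(0, dc))
        b_cols = slice(max(0, dc), ncols - max(0, -dc))
        a_idx = node_index[a_rows, a_cols]
        b_idx = node_index[b_rows, b_cols]
        a_r = r[a_rows, a_cols]
        b_r = r[b_rows, b_cols]
        both = (a_idx >= 0) & (b_idx >= 0)
        edge_i.append(a_idx[both])
        edge_j.append(b_idx[both])
        cond.append(2.0 / (dist * (a_r[both] + b_r[both])))
    edges = np.column_stack([np.concatenate(edge_i), np.concatenate(edge_j)])
    return ConductanceGraph(
        grid=resistance,
        node_index=node_index,
        nodes_rc=nodes_rc,
        edges=edges,
        conductances=np.concatenate(cond),
    )


@dataclass
class CircuitProblem:
    """One pairwise source/ground current-flow problem."""

    resistance: RasterGrid
    source_cell: tuple[int, int]
    ground_cell: tuple[int, int]
    injection: float = 1.0
    tolerance: float = 1e-8

    def __post_init__(self) -> None:
        if tuple(self.source_cell) == tuple(self.ground_cell):
            raise ValueError("source and ground must differ")
        for name in ("source_cell", "ground_cell"):
            rr, cc = getattr(self, name)
            if not (0 <= rr < self.resistance.nrows and 0 <= cc < self.resistance.ncols):
                raise ValueError(f"{name} outside the raster")
            if not np.isfinite(self.resistance.data[rr, cc]):
                raise ValueError(f"{name} lies on a nodata cell")


@dataclass
class CircuitSolution:
    """Voltages, branch currents and current-density map of one solve."""

    graph: ConductanceGraph
    voltages: np.ndarray  # per node, ground = 0
    branch_currents: np.ndarray  # per edge, signed, i->j positive
    current_map: RasterGrid
    effective_resistance: float
    solver_residual: float
    source_node: int
    ground_node: int
    kirchhoff_residual: float = field(default=np.nan)


def solve(problem: CircuitProblem, graph: ConductanceGraph | None = None) -> CircuitSolution:
    """Solve the grounded Laplacian system for one source/ground pair.

    Node current density is the half-sum of absolute incident branch
    currents at interior nodes (each unit of through-flow counted once);
    the source and ground cells report the injection itself.
    """
    if graph is None:
        graph = build_graph(problem.resistance)
    src = graph.node_index[problem.source_cell]
    gnd = graph.node_index[problem.ground_cell]
    if src < 0 or gnd < 0:
        raise ValueError("terminal cell is not a graph node")

    lap = graph.laplacian()
    n_comp, labels = connected_components(lap, directed=False)
    if labels[src] != labels[gnd]:
        sizes = np.bincount(labels)
        raise DisconnectedTerminalsError(
            f"source (component of {sizes[labels[src]]} cells) and ground "
            f"(component of {sizes[labels[gnd]]} cells) are not connected"
        )

    n = graph.n_nodes
    keep = np.arange(n) != gnd
    reduced = lap[keep][:, keep].tocsc()
    b = np.zeros(n)
    b[src] = problem.injection
    v = np.zeros(n)
    lu = splu(reduced)
    v[keep] = lu.solve(b[keep])

    residual = np.linalg.norm(reduced @ v[keep] - b[keep]) / max(
        np.linalg.norm(b[keep]), 1e-300
    )
    if residual > problem.tolerance:
        raise RuntimeError(
            f"solver residual {residual:.3e} exceeds tolerance {problem.tolerance:.3e}"
        )

    i_edge = graph.conductances * (v[graph.edges[:, 0]] - v[graph.edges[:, 1]])
    abs_inflow = np.zeros(n)
    np.add.at(abs_inflow, graph.edges[:, 0], np.abs(i_edge))
    np.add.at(abs_inflow, graph.edges[:, 1], np.abs(i_edge))
    density = abs_inflow / 2.0
    density[src] = problem.injection
    density[gnd] = problem.injection

    net = np.zeros(n)
    np.add.at(net, graph.edges[:, 0], -i_edge)
    np.add.at(net, graph.edges[:, 1], i_edge)
    net[src] += problem.injection
    net[gnd] -= problem.injection
    kirchhoff = float(np.max(np.abs(net)))

    cm = np.full(problem.resistance.shape, np.nan)
    cm[tuple(graph.nodes_rc.T)] = density
    current_map = problem.resistance.like(cm)

    return CircuitSolution(
        graph=graph,
        voltages=v,
        branch_currents=i_edge,
        current_map=current_map,
        effective_resistance=float(v[src] / problem.injection),
        solver_residual=float(residual),
        source_node=int(src),
        ground_node=int(gnd),
        kirchhoff_residual=kirchhoff,
    )


def snap_to_valid(
    grid: RasterGrid, x: float, y: float, max_radius_cells: int = 5
) -> tuple[int, int]:
    """Containing cell of (x, y), snapped to the nearest valid cell.

    Searches outward up to ``max_radius_cells``; raises :class:`SnapError`
    if no valid cell lies within that radius.
    """
    row, col = grid.xy_to_rowcol(x, y)
    row = int(np.clip(row, 0, grid.nrows - 1))
    col = int(np.clip(col, 0, grid.ncols - 1))
    if grid.valid[row, col]:
        return row, col
    best = None
    best_d2 = np.inf
    R = max_radius_cells
    for rr in range(max(0, row - R), min(grid.nrows, row + R + 1)):
        for cc in range(max(0, col - R), min(grid.ncols, col + R + 1)):
            if grid.valid[rr, cc]:
                d2 = (rr - row) ** 2 + (cc - col) ** 2
                if d2 < best_d2:
                    best, best_d2 = (rr, cc), d2
    if best is None or best_d2 > R**2:
        raise SnapError(
            f"no valid cell within {max_radius_cells} cells of ({x:.2f}, {y:.2f})"
        )
    return best


def individual_current_map(
    surface: RasterGrid,
    start_point: tuple[float, float],
    end_point: tuple[float, float],
    graph: ConductanceGraph | None = None,
    tolerance: float = 1e-8,
    max_snap_cells: int = 5,
) -> CircuitSolution:
    """Current map for one migration: start fix = source, end fix = ground."""
    src = snap_to_valid(surface, *start_point, max_radius_cells=max_snap_cells)
    gnd = snap_to_valid(surface, *end_point, max_radius_cells=max_snap_cells)
    if src == gnd:
        raise ValueError("start and end snap to the same cell")
    problem = CircuitProblem(
        resistance=surface, source_cell=src, ground_cell=gnd, tolerance=tolerance
    )
    return solve(problem, graph=graph)
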