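"""Circuit-theory connectivity on raster resistance surfaces.

A resistance raster is discretized into a conductance graph (cells = nodes,
neighbor edges = resistors); effective resistance between node pairs is the
circuit-theoretic distance used as the "effective distance" predictor in
isolation-by-resistance models, and per-cell current density under unit
current injection maps where gene flow concentrates.  The omnidirectional map
sums current over all pairs of nodes placed regularly along the map periphery,
revealing corridors and pinch points without choosing focal populations.

All solves go through a sparse Cholesky-style factorization of the grounded
graph Laplacian (one node per connected component held at zero volts).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse import csgraph
from scipy.sparse.linalg import splu

from .rasters import RasterLayer, rescale_to_range


@dataclass
class ConductanceGraph:
    """Undirected graph with positive edge conductances.

    ``edges`` is (E, 2) int node pairs, ``conductance`` (E,) > 0.  For graphs
    built from a raster, ``grid_shape`` and ``node_rc`` map node ids back to
    cells (row-major over unmasked cells).
    """

    n_nodes: int
    edges: np.ndarray
    conductance: np.ndarray
    grid_shape: tuple[int, int] | None = None
    node_rc: np.ndarray | None = None      # (n_nodes, 2) row, col
    _labels: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        self.conductance = np.asarray(self.conductance, dtype=float)
        if np.any(self.conductance <= 0):
            raise ValueError("conductances must be positive")
        if np.any(self.edges[:, 0] == self.edges[:, 1]):
            raise ValueError("self-edges are not allowed")

    def adjacency(self) -> sparse.csr_matrix:
        i, j = self.edges.T
        c = self.conductance
        A = sparse.coo_matrix(
            (np.r_[c, c], (np.r_[i, j], np.r_[j, i])),
            shape=(self.n_nodes, self.n_nodes))
        return A.tocsr()

    def laplacian(self) -> sparse.csr_matrix:
        A = self.adjacency()
        deg = np.asarray(A.sum(axis=1)).ravel()
        return sparse.diags(deg) - A

    def components(self) -> np.ndarray:
        if self._labels is None:
            _, labels = csgraph.connected_components(self.adjacency(),
                                                     directed=False)
            self._labels = labels
        return self._labels


def raster_to_graph(resistance: RasterLayer,
                    connectivity: int = 8) -> ConductanceGraph:
    """Discretize a resistance raster into a conductance graph.

    Nodes are unmasked cells; the conductance of an orthogonal edge is the
    mean of the two cell conductances (1/r), and diagonal edges (8-neighbor
    scheme) are additionally divided by √2 to correct for path length.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    vals = resistance.values
    mask = resistance.mask
    bad = mask & ~(vals > 0)
    if np.any(bad):
        r, c = np.argwhere(bad)[0]
        raise ValueError(f"nonpositive resistance at cell ({r}, {c})")
    nr, nc = vals.shape
    node_id = -np.ones((nr, nc), dtype=np.int64)
    rows, cols = np.nonzero(mask)
    node_id[rows, cols] = np.arange(rows.size)
    g = np.where(mask, 1.0 / np.where(mask, vals, 1.0), 0.0)

    offsets = [(0, 1, 1.0), (1, 0, 1.0)]
    if connectivity == 8:
        offsets += [(1, 1, 1.0 / np.sqrt(2)), (1, -1, 1.0 / np.sqrt(2))]
    ei, ej, ec = [], [], []
    for dr, dc, w in offsets:
        r0 = slice(max(0, -dr), nr - max(0, dr))
        c0 = slice(max(0, -dc), nc - max(0, dc))
        r1 = slice(max(0, dr), nr + min(0, dr))
        c1 = slice(max(0, dc), nc + min(0, dc))
        both = mask[r0, c0] & mask[r1, c1]
        a = node_id[r0, c0][both]
        b = node_id[r1, c1][both]
        cond = 0.5 * (g[r0, c0][both] + g[r1, c1][both]) * w
        ei.append(a)
        ej.append(b)
        ec.append(cond)
    edges = np.column_stack([np.concatenate(ei), np.concatenate(ej)])
    return ConductanceGraph(rows.size, edges, np.concatenate(ec),
                            grid_shape=(nr, nc),
                            node_rc=np.column_stack([rows, cols]))


class GroundedSolver:
    """Factorized solve of L v = b with one grounded node per component."""

    def __init__(self, graph: ConductanceGraph):
        self.graph = graph
        labels = graph.components()
        self.labels = labels
        n = graph.n_nodes
        # ground = first node of each component
        grounds = np.full(labels.max() + 1, -1, dtype=np.int64)
        for i in range(n):
            if grounds[labels[i]] < 0:
                grounds[labels[i]] = i
        self.grounds = grounds
        keep = np.ones(n, dtype=bool)
        keep[grounds] = False
        self.keep = keep
        self.reduced_index = -np.ones(n, dtype=np.int64)
        self.reduced_index[keep] = np.arange(keep.sum())
        L = graph.laplacian().tocsc()
        Lr = L[keep][:, keep].tocsc()
        self._lu = splu(Lr) if keep.sum() else None

    def solve(self, b: np.ndarray) -> np.ndarray:
        """Voltages for injection vector b (grounded nodes fixed at 0)."""
        v = np.zeros(self.graph.n_nodes)
        if self._lu is not None:
            v[self.keep] = self._lu.solve(np.asarray(b, float)[self.keep])
        return v

    def columns(self, nodes) -> np.ndarray:
        """Grounded-inverse columns G[:, k] for each requested node."""
        out = np.zeros((len(nodes), self.graph.n_nodes))
        for k, nd in enumerate(nodes):
            if self.keep[nd]:
                e = np.zeros(self.graph.n_nodes)
                e[nd] = 1.0
                out[k] = self.solve(e)
        return out


INF_DISTANCE = np.inf


def effective_resistance(g: ConductanceGraph, pairs) -> np.ndarray:
    """Effective (resistance) distance for each node pair.

    R_ij is the voltage at i when unit current is injected at i and extracted
    at a grounded j; computed via grounded-inverse columns as
    R_ij = G_ii + G_jj − 2 G_ij.  Pairs in different components get an
    infinite-distance sentinel with a warning.
    """
    pairs = np.asarray(pairs, dtype=np.int64).reshape(-1, 2)
    solver = GroundedSolver(g)
    labels = solver.labels
    nodes = np.unique(pairs)
    G = {nd: col for nd, col in zip(nodes, solver.columns(nodes))}
    out = np.empty(len(pairs))
    n_disc = 0
    for k, (i, j) in enumerate(pairs):
        if labels[i] != labels[j]:
            out[k] = INF_DISTANCE
            n_disc += 1
            continue
        out[k] = G[i][i] + G[j][j] - 2.0 * G[i][j]
    if n_disc:
        warnings.warn(f"{n_disc} node pairs span disconnected components; "
                      "returned inf")
    return out


def pairwise_effective_resistance(g: ConductanceGraph,
                                  nodes) -> np.ndarray:
    """Dense symmetric effective-resistance matrix among ``nodes``."""
    nodes = np.asarray(nodes, dtype=np.int64)
    solver = GroundedSolver(g)
    labels = solver.labels
    G = solver.columns(nodes)
    m = len(nodes)
    R = np.zeros((m, m))
    diag = np.array([G[k][nodes[k]] for k in range(m)])
    for a in range(m):
        for b in range(a + 1, m):
            if labels[nodes[a]] != labels[nodes[b]]:
                R[a, b] = R[b, a] = INF_DISTANCE
            else:
                R[a, b] = R[b, a] = diag[a] + diag[b] - 2.0 * G[a][nodes[b]]
    return R


def _node_currents(g: ConductanceGraph, v: np.ndarray,
                   terminals: dict[int, float]) -> np.ndarray:
    """Per-node current: half the sum of absolute incident edge currents plus
    half the absolute injected current at terminal nodes."""
    i, j = g.edges.T
    ie = g.conductance * (v[i] - v[j])
    out = np.zeros(g.n_nodes)
    np.add.at(out, i, np.abs(ie))
    np.add.at(out, j, np.abs(ie))
    for nd, inj in terminals.items():
        out[nd] += abs(inj)
    return 0.5 * out


def current_density(g: ConductanceGraph, source: int, ground: int):
    """Per-cell current magnitude for unit current from ``source`` to
    ``ground``.  Returns (node currents, node voltages)."""
    if source == ground:
        raise ValueError("source and ground must differ")
    labels = g.components()
    if labels[source] != labels[ground]:
        raise ValueError("source and ground are in different components")
    solver = GroundedSolver(g)
    Gs, Gg = solver.columns([source, ground])
    v = Gs - Gg
    cur = _node_currents(g, v, {source: 1.0, ground: 1.0})
    return cur, v


def _boundary_ring_nodes(g: ConductanceGraph) -> np.ndarray:
    """Unmasked cells on the outer ring of the grid, ordered clockwise from
    the top-left corner (the map periphery)."""
    if g.grid_shape is None:
        raise ValueError("graph was not built from a raster")
    nr, nc = g.grid_shape
    node_id = -np.ones((nr, nc), dtype=np.int64)
    node_id[g.node_rc[:, 0], g.node_rc[:, 1]] = np.arange(g.n_nodes)
    ring = []
    ring += [(0, c) for c in range(nc)]
    ring += [(r, nc - 1) for r in range(1, nr)]
    ring += [(nr - 1, c) for c in range(nc - 2, -1, -1)]
    ring += [(r, 0) for r in range(nr - 2, 0, -1)]
    ids = [node_id[r, c] for r, c in ring if node_id[r, c] >= 0]
    return np.asarray(ids, dtype=np.int64)


def place_perimeter_nodes(g: ConductanceGraph, n_nodes: int) -> np.ndarray:
    """``n_nodes`` nodes at equal arc-length spacing along the periphery."""
    ring = _boundary_ring_nodes(g)
    if ring.size < n_nodes:
        warnings.warn(f"boundary has only {ring.size} cells; reducing node "
                      f"count from {n_nodes}")
        n_nodes = ring.size
    idx = np.floor(np.arange(n_nodes) * ring.size / n_nodes).astype(int)
    return ring[idx]


def omnidirectional_current(resistance: RasterLayer, n_nodes: int = 100,
                            connectivity: int = 8) -> RasterLayer:
    """Omnidirectional (all-pairs perimeter) current-density map.

    The surface is linearly rescaled to [1, 100]; ``n_nodes`` terminals are
    placed regularly along the unmasked map boundary; per-cell current is
    summed over all terminal pairs; the summed map is natural-log-transformed
    and standardized to mean zero over the unmasked cells, so 0 marks average
    log current and positive/negative values above/below-average flow.
    """
    if n_nodes < 3:
        raise ValueError("need at least 3 perimeter nodes")
    res = rescale_to_range(resistance, 1.0, 100.0)
    g = raster_to_graph(res, connectivity=connectivity)
    nodes = place_perimeter_nodes(g, n_nodes)
    solver = GroundedSolver(g)
    labels = solver.labels
    V = solver.columns(nodes)

    i, j = g.edges.T
    E = len(i)
    B_abs = sparse.coo_matrix(
        (np.ones(2 * E), (np.r_[i, j], np.r_[np.arange(E), np.arange(E)])),
        shape=(g.n_nodes, E)).tocsr()

    total = np.zeros(g.n_nodes)
    skipped = 0
    for a in range(len(nodes)):
        for b in range(a + 1, len(nodes)):
            if labels[nodes[a]] != labels[nodes[b]]:
                skipped += 1
                continue
            v = V[a] - V[b]
            absI = np.abs(g.conductance * (v[i] - v[j]))
            cur = 0.5 * (B_abs @ absI)
            cur[nodes[a]] += 0.5
            cur[nodes[b]] += 0.5
            total += cur
    if skipped:
        warnings.warn(f"{skipped} perimeter pairs in different components "
                      "were skipped")

    out = np.full(res.shape, np.nan)
    omask = np.zeros(res.shape, dtype=bool)
    pos = total > 0
    rr, cc = g.node_rc[pos, 0], g.node_rc[pos, 1]
    out[rr, cc] = np.log(total[pos])
    omask[rr, cc] = True
    out[omask] -= out[omask].mean()
    return res.copy_with(values=out, mask=omask, kind="continuous")
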