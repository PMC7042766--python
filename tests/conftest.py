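import numpy as np
import pytest

from landconn.genetics import GenotypeTable
from landconn.rasters import RasterLayer


@pytest.fixture
def two_locus_pair():
    """Two individuals over two loci: Dps = (0.5 + 1.0)/2 = 0.75."""
    a = np.array([["A", "A"], ["C", "D"]], dtype=object)
    b = np.array([["A", "B"], ["C", "D"]], dtype=object)
    return a, b


@pytest.fixture
def small_table():
    """Three individuals, two loci, one with a missing call at locus 2."""
    alleles = np.array([
        [["A", "B"], ["C", "C"]],
        [["A", "A"], ["", ""]],
        [["B", "B"], ["C", "D"]],
    ], dtype=object)
    coords = np.array([[0.0, 0.0], [1000.0, 0.0], [0.0, 1000.0]])
    return GenotypeTable(["i1", "i2", "i3"], coords, alleles)


@pytest.fixture
def uniform_raster():
    return RasterLayer(np.ones((9, 9)), cell_size=100.0, origin=(0.0, 900.0))


def make_random_graph(rng, n_nodes=20, extra_edges=15):
    """Random connected graph with positive conductances (spanning tree plus
    random extra edges)."""
    from landconn.circuits import ConductanceGraph
    edges = []
    for i in range(1, n_nodes):
        edges.append((rng.integers(0, i), i))
    for _ in range(extra_edges):
        a, b = rng.integers(0, n_nodes, size=2)
        if a != b:
            edges.append((min(a, b), max(a, b)))
    edges = np.array(list(dict.fromkeys(map(tuple, edges))))
    cond = rng.uniform(0.2, 3.0, len(edges))
    return ConductanceGraph(n_nodes, edges, cond)
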