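import networkx as nx
import numpy as np
import pytest

from pathcolor.expression import ExpressionMatrix
from pathcolor.netbuild import WEIGHT_KEY


def make_matrix(rows, gene_ids=None, sample_ids=None):
    """ExpressionMatrix from a list of rows; NaN entries become masked."""
    values = np.asarray(rows, dtype=float)
    mask = np.isnan(values)
    values = np.where(mask, 0.0, values)
    n_genes, n_samples = values.shape
    gene_ids = gene_ids or [f"G{i:02d}" for i in range(n_genes)]
    sample_ids = sample_ids or [f"S{j:02d}" for j in range(n_samples)]
    return ExpressionMatrix(gene_ids, sample_ids, values, mask)


def weighted_graph(edges):
    """Graph from (u, v, w) triples."""
    g = nx.Graph()
    for u, v, w in edges:
        g.add_edge(u, v, **{WEIGHT_KEY: float(w)})
    return g


def random_weighted_graph(rng, n_max=12, p=0.4):
    n = int(rng.integers(4, n_max + 1))
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
    net = nx.relabel_nodes(g, {i: f"N{i:02d}" for i in g})
    for u, v in net.edges():
        net[u][v][WEIGHT_KEY] = float(rng.uniform(0.1, 3.0))
    return net


@pytest.fixture
def path_graph():
    """A -- B -- C -- D -- E with unit weights."""
    return weighted_graph(
        [("A", "B", 1), ("B", "C", 1), ("C", "D", 1), ("D", "E", 1)]
    )


@pytest.fixture
def star_graph():
    """Hub H with five unit-weight leaves."""
    return weighted_graph([("H", f"L{i}", 1) for i in range(5)])


@pytest.fixture
def triangle_graph():
    return weighted_graph([("A", "B", 1), ("B", "C", 1), ("A", "C", 1)])
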