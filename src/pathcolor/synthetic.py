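"""Synthetic benchmark instances: scale-free networks, planted signalling
paths, correlated expression, and location annotations.

The generator emulates the inputs the detector consumes in practice: a
preferential-attachment (Barabasi-Albert) interaction network whose degree
distribution is scale-free; one planted membrane-to-nucleus path whose genes
share a latent expression factor and are therefore highly correlated; and
independent noise expression for every other gene.  After standard weighting
the planted path is, with high probability, the unique minimum-weight l-path
between its endpoints, which gives every downstream module a ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .expression import ExpressionMatrix
from .netbuild import assign_weights, locations_from_graph

__all__ = [
    "generate_scale_free",
    "plant_path",
    "generate_expression",
    "planted_instance",
    "PlantedInstance",
]


def generate_scale_free(n: int, m_attach: int = 2, seed: int = 0) -> nx.Graph:
    """Connected preferential-attachment graph with ``n`` nodes.

    Each new node attaches to ``m_attach`` existing nodes with probability
    proportional to degree, producing the heavy-tailed degree distribution
    of real interaction networks.  Node names are ``P0000`` style strings.
    """
    if not n > m_attach >= 1:
        raise ValueError(f"need n > m_attach >= 1, got n={n}, m_attach={m_attach}")
    g = nx.barabasi_albert_graph(n, m_attach, seed=seed)
    return nx.relabel_nodes(g, {i: f"P{i:04d}" for i in g.nodes()})


def plant_path(net: nx.Graph, l: int, seed: int = 0) -> list[str]:
    """Plant a simple membrane-to-nucleus path of ``l`` nodes in the network.

    Picks ``l`` distinct nodes at random, adds any missing consecutive
    edges, and tags the first node membrane (rank 1), the last nucleus
    (rank 3) and the interior cytoplasm (rank 2) via the ``location_rank``
    node attribute, so the path satisfies the location-monotonicity
    constraint by construction.  Returns the ordered node list.
    """
    n = net.number_of_nodes()
    if l > n:
        raise ValueError(f"cannot plant a path of {l} nodes in a {n}-node network")
    if l < 2:
        raise ValueError("l must be >= 2")
    rng = np.random.default_rng(seed)
    nodes = sorted(net.nodes())
    path = [nodes[i] for i in rng.choice(n, size=l, replace=False)]
    nx.add_path(net, path)
    net.nodes[path[0]]["location_rank"] = 1
    net.nodes[path[-1]]["location_rank"] = 3
    for v in path[1:-1]:
        net.nodes[v]["location_rank"] = 2
    return path


def generate_expression(
    net: nx.Graph,
    planted: list[str],
    n_samples: int = 200,
    r_on: float = 0.9,
    noise_sd: float = 1.0,
    missing_frac: float = 0.0,
    seed: int = 0,
) -> ExpressionMatrix:
    """Expression matrix with a shared latent factor on the planted genes.

    Planted genes follow x = lambda * z + noise, with the loading lambda
    solving lambda^2 / (lambda^2 + noise_sd^2) = r_on, so any two planted
    genes have expected correlation ``r_on``.  All other genes are
    independent Gaussian noise of matching variance.  ``missing_frac`` of
    cells are masked uniformly at random.
    """
    if not 0.0 < r_on <= 1.0:
        raise ValueError("r_on must be in (0, 1]")
    if not 0.0 <= missing_frac < 1.0:
        raise ValueError("missing_frac must be in [0, 1)")
    rng = np.random.default_rng(seed)
    genes = sorted(net.nodes())
    planted_set = set(planted)
    n_genes = len(genes)
    if r_on == 1.0:
        lam, eff_noise = 1.0, 0.0
    else:
        lam = noise_sd * np.sqrt(r_on / (1.0 - r_on))
        eff_noise = noise_sd
    total_sd = float(np.hypot(lam, eff_noise))

    z = rng.standard_normal(n_samples)  # shared latent factor
    values = np.empty((n_genes, n_samples))
    for i, g in enumerate(genes):
        if g in planted_set:
            values[i] = lam * z + eff_noise * rng.standard_normal(n_samples)
        else:
            values[i] = total_sd * rng.standard_normal(n_samples)
    mask = rng.random((n_genes, n_samples)) < missing_frac
    return ExpressionMatrix(genes, [f"S{j:03d}" for j in range(n_samples)], values, mask)


@dataclass
class PlantedInstance:
    """A fully wired synthetic benchmark: weighted network + ground truth."""

    net: nx.Graph
    planted: list[str]
    matrix: ExpressionMatrix
    locations: dict[str, int | None]


def planted_instance(
    n: int = 60,
    l: int = 7,
    m_attach: int = 2,
    n_samples: int = 200,
    r_on: float = 0.9,
    seed: int = 0,
) -> PlantedInstance:
    """Generate network, planted path and expression, and assign edge weights."""
    ss = np.random.SeedSequence(seed)
    s_net, s_path, s_expr = (int(np.random.default_rng(c).integers(2**31)) for c in ss.spawn(3))
    net = generate_scale_free(n, m_attach, seed=s_net)
    planted = plant_path(net, l, seed=s_path)
    matrix = generate_expression(net, planted, n_samples=n_samples, r_on=r_on, seed=s_expr)
    assign_weights(net, matrix)
    return PlantedInstance(net, planted, matrix, locations_from_graph(net))
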