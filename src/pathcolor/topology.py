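"""Network-topology statistics: degrees, hubs, articulation points, hop diameter.

Scale-free interaction networks concentrate connectivity in a few hubs, and
articulation points are the bottlenecks through which signalling must pass.
Both drive the topology-aware coloring.  The hop diameter (longest shortest
path over all node pairs) sets the default search length and color count:
by the small-world property any two proteins are linked within that many
steps.
"""

from __future__ import annotations

import networkx as nx

__all__ = [
    "DEFAULT_HUB_DEGREE",
    "node_degrees",
    "hubs",
    "articulation_points",
    "longest_shortest_path",
]

#: Degree at or above which a node counts as a hub.
DEFAULT_HUB_DEGREE = 8


def node_degrees(net: nx.Graph) -> dict[str, int]:
    """Degree of every node (number of adjacent edges)."""
    return dict(net.degree())


def hubs(net: nx.Graph, degree_threshold: int = DEFAULT_HUB_DEGREE) -> set[str]:
    """Nodes with degree >= ``degree_threshold``."""
    return {v for v, d in net.degree() if d >= degree_threshold}


def articulation_points(net: nx.Graph) -> set[str]:
    """Nodes whose removal increases the number of connected components.

    Computed by the linear-time DFS low-link method.
    """
    return set(nx.articulation_points(net))


def longest_shortest_path(net: nx.Graph) -> int:
    """Hop-count diameter of the largest connected component.

    The maximum over node pairs of the unweighted shortest-path length; this
    is the number of edges, so a path of 5 nodes yields 4.  Pairs in
    different components are ignored: the diameter is taken on the largest
    component.  This value bounds how many steps separate any two reachable
    proteins and is the default path length / color count for the search.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("longest_shortest_path of an empty network is undefined")
    component = max(nx.connected_components(net), key=len)
    if len(component) == 1:
        return 0
    return nx.diameter(net.subgraph(component))
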