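"""Build the weighted protein-interaction network.

Nodes are proteins, edges are physical interactions, and each edge carries a
nonnegative weight -log(max(|r|, eps)) where r is the Pearson correlation of
the two genes' expression profiles.  High co-expression means low weight, so
biologically supported paths are minimum-weight paths.  Edges with no usable
expression evidence get the cap weight -log(eps), keeping the network's
connectivity (and hence its articulation structure) intact.
"""

from __future__ import annotations

import logging
import math

import networkx as nx
import pandas as pd

from .expression import ExpressionMatrix, UndefinedCorrelationError, pairwise_correlation

logger = logging.getLogger(__name__)

__all__ = [
    "WEIGHT_KEY",
    "LOCATION_RANKS",
    "DEFAULT_EPSILON",
    "read_edge_list",
    "write_edge_list",
    "assign_weights",
    "cap_weight",
    "read_locations",
    "locations_from_graph",
]

WEIGHT_KEY = "weight"
DEFAULT_EPSILON = 1e-4

#: Ordered cellular compartments for the location-monotonicity constraint.
#: ``intracellular`` (and any unannotated protein) is a wildcard, compatible
#: with every rank, and is represented as ``None`` in a location map.
LOCATION_RANKS: dict[str, int | None] = {
    "membrane": 1,
    "cytoplasm": 2,
    "nucleus": 3,
    "intracellular": None,
}


def cap_weight(epsilon: float = DEFAULT_EPSILON, base: str = "e") -> float:
    """The weight assigned when correlation evidence is absent or undefined."""
    return -_log(epsilon, base)


def _log(x: float, base: str) -> float:
    if base == "e":
        return math.log(x)
    if base == "10":
        return math.log10(x)
    raise ValueError(f"unknown log base {base!r} (use 'e' or '10')")


def read_edge_list(path) -> nx.Graph:
    """Read an undirected edge list from a 2+ column TSV.

    Duplicate rows and reversed duplicates collapse to one edge; self-loops
    are dropped (count logged).  An optional third numeric column is kept as
    a precomputed weight; otherwise weights stay unset (NaN) until
    :func:`assign_weights`.
    """
    net = nx.Graph()
    n_loops = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2 or not parts[0].strip() or not parts[1].strip():
                raise ValueError(f"{path}: malformed edge row at line {lineno}: {line!r}")
            u, v = parts[0].strip(), parts[1].strip()
            if u == v:
                n_loops += 1
                net.add_node(u)
                continue
            w = float("nan")
            if len(parts) >= 3 and parts[2].strip():
                try:
                    w = float(parts[2])
                except ValueError:
                    raise ValueError(
                        f"{path}: non-numeric weight at line {lineno}: {parts[2]!r}"
                    ) from None
            net.add_edge(u, v, **{WEIGHT_KEY: w})
    if n_loops:
        logger.info("dropped %d self-loop row(s) while reading %s", n_loops, path)
    return net


def write_edge_list(net: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        for u, v, data in sorted(net.edges(data=True)):
            w = data.get(WEIGHT_KEY, float("nan"))
            fh.write(f"{u}\t{v}\t{w:.6g}\n")


def assign_weights(
    net: nx.Graph,
    matrix: ExpressionMatrix,
    epsilon: float = DEFAULT_EPSILON,
    base: str = "e",
    drop_unsupported: bool = False,
) -> nx.Graph:
    """Weight every edge by -log(max(|Pearson r|, epsilon)).

    The absolute value captures inhibition (negative correlation) as well as
    activation.  ``epsilon`` floors |r| so weights stay finite; edges whose
    endpoints lack expression data, or whose correlation is undefined, get
    the cap weight -log(epsilon) (or are deleted when ``drop_unsupported``).
    Operates in place and returns the graph; recomputing with the same matrix
    is idempotent.
    """
    if not 0.0 < epsilon < 1.0:
        raise ValueError("epsilon must be in (0, 1)")
    cap = cap_weight(epsilon, base)
    n_capped = 0
    to_drop = []
    for u, v in net.edges():
        r = None
        if u in matrix and v in matrix:
            try:
                r = pairwise_correlation(matrix, u, v)
            except UndefinedCorrelationError:
                r = None
        if r is None:
            n_capped += 1
            if drop_unsupported:
                to_drop.append((u, v))
                continue
            net[u][v][WEIGHT_KEY] = cap
        else:
            net[u][v][WEIGHT_KEY] = -_log(max(abs(r), epsilon), base)
    net.remove_edges_from(to_drop)
    if n_capped:
        verb = "dropped" if drop_unsupported else "capped at -log(eps)"
        logger.info("%d edge(s) without usable expression evidence %s", n_capped, verb)
    return net


def read_locations(path) -> dict[str, int | None]:
    """Read a protein -> location-rank map from a two-column TSV.

    The second column is an integer rank or a compartment name from
    :data:`LOCATION_RANKS`.  Wildcard compartments map to ``None``.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=["protein", "location"], dtype=str)
    ranks: dict[str, int | None] = {}
    for protein, loc in zip(df["protein"], df["location"]):
        loc = str(loc).strip()
        if loc.lstrip("-").isdigit():
            ranks[str(protein)] = int(loc)
        elif loc.lower() in LOCATION_RANKS:
            ranks[str(protein)] = LOCATION_RANKS[loc.lower()]
        else:
            raise ValueError(f"unknown compartment {loc!r} for protein {protein!r}")
    return ranks


def locations_from_graph(net: nx.Graph) -> dict[str, int | None]:
    """Collect ``location_rank`` node attributes into a location map."""
    return {
        v: data["location_rank"] for v, data in net.nodes(data=True) if "location_rank" in data
    }
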