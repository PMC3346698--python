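"""Topology-aware color-coding.

Color-coding turns simple-path search into colorful-path search: assign each
node one of k colors and look for paths whose nodes carry pairwise-distinct
colors.  Under uniform random coloring a fixed k-node path is colorful with
probability k!/k^k > e^-k, so many independent colorings are needed before a
target path is seen.  Biological networks are scale-free: paths of interest
overwhelmingly run through hubs and articulation points, and a random
coloring that gives a hub the same color as a neighbour silently removes all
paths through that pair.  The scheme here therefore colors nodes in
descending-degree order, steering every high-degree node and every
articulation point away from its neighbours' colors, while leaves — which no
simple path crosses — are allowed (by default, forced) to copy their single
neighbour's color, conserving the color budget for the interior.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import networkx as nx
import numpy as np

from .topology import DEFAULT_HUB_DEGREE, articulation_points, hubs

__all__ = [
    "Coloring",
    "ColoringConstraintsReport",
    "color_network",
    "uniform_coloring",
    "constraints_report",
    "is_colorful",
    "colorful_probability_bound",
    "required_repetitions",
    "success_rate",
]


@dataclass(frozen=True)
class Coloring:
    """A node -> color assignment over colors 1..k."""

    color: dict[str, int]
    k: int
    mode: str = "paper_faithful"

    def __post_init__(self) -> None:
        bad = {v: c for v, c in self.color.items() if not 1 <= c <= self.k}
        if bad:
            raise ValueError(f"colors outside 1..{self.k}: {dict(list(bad.items())[:5])}")


@dataclass(frozen=True)
class ColoringConstraintsReport:
    """QA counts of color collisions at the nodes the scheme protects."""

    hub_violations: int
    articulation_violations: int


def color_network(
    net: nx.Graph,
    k: int,
    degree_threshold: int = DEFAULT_HUB_DEGREE,
    seed: int = 0,
    mode: str = "paper_faithful",
) -> Coloring:
    """Color the network with k colors, protecting hubs and articulation points.

    Nodes are processed in descending-degree order (ties by node id).  A node
    of degree >= 2 draws uniformly among the colors not used by its
    already-colored neighbours, falling back to a uniform draw over all k
    colors when none is free.  Degree-1 nodes (leaves) copy their single
    neighbour's color in ``paper_faithful`` mode, or draw a color different
    from it in ``strict_leaf`` mode.  A final pass recolors every
    articulation point that still collides with a neighbour, whenever an
    unused color exists.

    All randomness flows from one generator seeded with ``seed``.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if mode not in ("paper_faithful", "strict_leaf"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    all_colors = list(range(1, k + 1))
    degree = dict(net.degree())
    order = sorted(net.nodes(), key=lambda v: (-degree[v], v))

    color: dict[str, int] = {}
    for v in order:
        neighbor_colors = {color[u] for u in net[v] if u in color}
        if degree[v] == 1:
            (u,) = net[v]
            if mode == "paper_faithful":
                color[v] = color[u] if u in color else int(rng.choice(all_colors))
            else:  # strict_leaf
                choices = [c for c in all_colors if u not in color or c != color[u]]
                color[v] = int(rng.choice(choices))
        elif degree[v] == 0:
            color[v] = int(rng.choice(all_colors))
        else:
            free = [c for c in all_colors if c not in neighbor_colors]
            color[v] = int(rng.choice(free if free else all_colors))

    # Recoloring pass: articulation points must differ from every neighbour
    # when the palette allows it.  In paper_faithful mode leaves deliberately
    # copy their neighbour's color, so degree-1 neighbours are not collisions.
    for v in sorted(articulation_points(net)):
        relevant = [u for u in net[v] if not (mode == "paper_faithful" and degree[u] == 1)]
        neighbor_colors = {color[u] for u in relevant}
        if color[v] in neighbor_colors:
            free = [c for c in all_colors if c not in {color[u] for u in net[v]}]
            if not free:
                free = [c for c in all_colors if c not in neighbor_colors]
            if free:
                color[v] = int(rng.choice(free))

    return Coloring(color, k, mode)


def uniform_coloring(net: nx.Graph, k: int, seed: int = 0) -> Coloring:
    """Plain randomized color-coding: every node draws uniformly from 1..k."""
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    nodes = sorted(net.nodes())
    draws = rng.integers(1, k + 1, size=len(nodes))
    return Coloring({v: int(c) for v, c in zip(nodes, draws)}, k, mode="uniform")


def constraints_report(
    net: nx.Graph, coloring: Coloring, degree_threshold: int = DEFAULT_HUB_DEGREE
) -> ColoringConstraintsReport:
    """Count hub-neighbour and articulation-neighbour color collisions.

    Counts only the collisions the scheme promises to avoid: in
    paper_faithful mode a leaf copies its neighbour's color on purpose, so
    degree-1 neighbours are excluded there.
    """
    color = coloring.color
    degree = dict(net.degree())

    def relevant(v):
        for u in net[v]:
            if coloring.mode == "paper_faithful" and degree[u] == 1:
                continue
            yield u

    hub_set = hubs(net, degree_threshold)
    ap_set = articulation_points(net)
    hub_viol = sum(1 for v in hub_set for u in relevant(v) if color[u] == color[v])
    ap_viol = sum(1 for v in ap_set for u in relevant(v) if color[u] == color[v])
    return ColoringConstraintsReport(hub_viol, ap_viol)


def is_colorful(path: Sequence[str], coloring: Coloring) -> bool:
    """True iff all node colors along the path are pairwise distinct."""
    try:
        colors = [coloring.color[v] for v in path]
    except KeyError as e:
        raise ValueError(f"uncolored node {e.args[0]!r} on path") from None
    return len(set(colors)) == len(colors)


def colorful_probability_bound(k: int) -> float:
    """Probability k!/k^k that a fixed k-node path is colorful under uniform
    coloring with k colors; always exceeds e^-k (Stirling)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return math.factorial(k) / k**k


def required_repetitions(k: int, failure_cap: float = 0.05) -> int:
    """Smallest t with (1 - e^-k)^t <= failure_cap.

    Each independent coloring misses a fixed k-node path with probability at
    most 1 - e^-k, so t = ceil(ln(failure_cap) / ln(1 - e^-k)) colorings cap
    the overall failure probability.  For k = 8 and a 5% cap this is 8929.
    """
    if failure_cap >= 1.0:
        return 0
    if failure_cap <= 0.0:
        raise ValueError("failure_cap must be in (0, 1)")
    return math.ceil(math.log(failure_cap) / math.log(1.0 - math.exp(-k)))


def success_rate(
    net: nx.Graph,
    colorer: Callable[[nx.Graph, int], Coloring],
    trials: int,
    l: int,
    start_set: Iterable[str],
    end_set: Iterable[str],
    seed: int = 0,
) -> float:
    """Fraction of colorings under which a colorful l-node path exists.

    Each trial samples a start node, an end node and a fresh coloring from
    ``colorer(net, trial_seed)``, then asks the search module (with an
    infinite bound) whether any colorful simple path of exactly ``l`` nodes
    connects them.  The endpoint sampling stream is independent of the
    coloring stream, so two colorers called with the same ``seed`` are
    evaluated on identical endpoint pairs (paired comparison).
    """
    from .pathsearch import colorful_path_exists

    if trials < 1:
        raise ValueError("trials must be >= 1")
    starts = sorted(set(start_set))
    ends = sorted(set(end_set))
    if not starts or not ends:
        raise ValueError("start_set and end_set must be non-empty")
    pair_ss, color_ss = np.random.SeedSequence(seed).spawn(2)
    pair_rng = np.random.default_rng(pair_ss)
    color_rng = np.random.default_rng(color_ss)
    n_ok = 0
    for _ in range(trials):
        s = starts[int(pair_rng.integers(len(starts)))]
        t = ends[int(pair_rng.integers(len(ends)))]
        for _retry in range(100):
            if s != t:
                break
            t = ends[int(pair_rng.integers(len(ends)))]
        coloring = colorer(net, int(color_rng.integers(2**31)))
        if s != t and colorful_path_exists(net, coloring, s, t, l):
            n_ok += 1
    return n_ok / trials
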