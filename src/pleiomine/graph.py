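"""Undirected weighted graph of trait-level item co-occurrence in rules.

Each rule contributes a clique over its body ∪ head; an edge's weight counts
the rules in which the pair co-occurs and ``max_lift`` records the largest
lift among those rules.  Vertex size in renderings is proportional to degree.
"""

from __future__ import annotations

import re
from itertools import combinations
from typing import Callable, Iterable

import networkx as nx

from .arm import AssociationRule

__all__ = ["build_graph", "neighbors", "export_graph", "read_graph", "render_graph"]

# greedy prefix: a single trailing digit is the level, so 'GLU605' -> 'GLU60'
_LEVEL_SUFFIX = re.compile(r"^(.*)(\d)$")


def collapse_item_to_trait(item: str) -> str:
    """Strip the trailing level digit: 'TG5' -> 'TG'. Items without one pass through."""
    m = _LEVEL_SUFFIX.match(item)
    return m.group(1) if m else item


def build_graph(
    rules: Iterable[AssociationRule],
    collapse: Callable[[str], str] | None = None,
) -> nx.Graph:
    """Clique-expand each rule into pairwise edges with additive weights.

    ``collapse`` optionally maps items to coarser vertices (e.g. merging all
    levels of one trait); self-loops arising from a collapse are dropped.
    """
    rules = list(rules)
    if not rules:
        raise ValueError("cannot build a graph from an empty rule set")
    g = nx.Graph()
    for rule in rules:
        items = sorted(rule.items)
        if collapse is not None:
            items = sorted({collapse(it) for it in items})
        g.add_nodes_from(items)
        for u, v in combinations(items, 2):
            if g.has_edge(u, v):
                g[u][v]["weight"] += 1
                g[u][v]["max_lift"] = max(g[u][v]["max_lift"], rule.lift)
            else:
                g.add_edge(u, v, weight=1, max_lift=rule.lift)
    for v in g.nodes:
        g.nodes[v]["degree"] = g.degree[v]
    return g


def neighbors(graph: nx.Graph, item: str) -> list[str]:
    """Neighbors of ``item`` ordered by edge weight descending, then name."""
    if item not in graph:
        raise KeyError(f"item {item!r} not in graph")
    return sorted(graph.neighbors(item), key=lambda v: (-graph[item][v]["weight"], v))


def export_graph(graph: nx.Graph, path, format: str = "graphml") -> None:
    if graph.number_of_nodes() == 0:
        raise ValueError("refusing to export an empty graph")
    if format == "graphml":
        nx.write_graphml(graph, path)
    elif format == "edge-list":
        with open(path, "w") as fh:
            for u, v, data in sorted(graph.edges(data=True)):
                fh.write(f"{u}\t{v}\t{data['weight']}\n")
    else:
        raise ValueError(f"unsupported graph format {format!r}")


def read_graph(path, format: str = "graphml") -> nx.Graph:
    if format == "graphml":
        g = nx.read_graphml(path)
        # GraphML round-trips ints as ints via type attrs, but normalize anyway
        for _, _, data in g.edges(data=True):
            data["weight"] = int(data["weight"])
        for v in g.nodes:
            if "degree" in g.nodes[v]:
                g.nodes[v]["degree"] = int(g.nodes[v]["degree"])
        return g
    if format == "edge-list":
        g = nx.Graph()
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                u, v, w = line.rstrip("\n").split("\t")
                g.add_edge(u, v, weight=int(w))
        for v in g.nodes:
            g.nodes[v]["degree"] = g.degree[v]
        return g
    raise ValueError(f"unsupported graph format {format!r}")


def render_graph(graph: nx.Graph, path, layout_seed: int = 0) -> None:
    """Spring-layout PNG with vertex size proportional to degree."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pos = nx.spring_layout(graph, seed=layout_seed)
    degrees = [graph.degree[v] for v in graph.nodes]
    sizes = [100 + 80 * d for d in degrees]
    weights = [graph[u][v]["weight"] for u, v in graph.edges]
    wmax = max(weights) if weights else 1
    fig, ax = plt.subplots(figsize=(10, 10))
    nx.draw_networkx(
        graph,
        pos=pos,
        ax=ax,
        node_size=sizes,
        width=[0.5 + 2.5 * w / wmax for w in weights],
        node_color="lightsteelblue",
        font_size=8,
    )
    ax.set_axis_off()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
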