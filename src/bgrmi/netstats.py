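"""Topological characterization of thresholded regulatory networks.

Three rankings are offered: transcriptional hubs (out-degree, the
number of predicted targets), transcriptional junctions (unnormalized
betweenness centrality — the number of directed shortest paths between
ordered gene pairs passing through a node, fractionally counted when
several shortest paths exist), and master regulators (PageRank).  For
the master-regulator ranking, edges are reversed by default before
computing PageRank: a regulator of large hubs then inherits its
targets' importance, whereas plain PageRank on regulator-to-target
edges would reward being heavily targeted instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

__all__ = [
    "DirectedNetwork",
    "out_degree_hubs",
    "betweenness",
    "pagerank",
    "from_edges",
]


@dataclass
class DirectedNetwork:
    """Simple directed graph with an optional sign per edge."""

    nodes: list[str]
    edges: list[tuple[str, str]]
    signs: dict[tuple[str, str], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.edges)) != len(self.edges):
            raise ValueError("duplicate edges")
        known = set(self.nodes)
        for u, v in self.edges:
            if u not in known or v not in known:
                raise ValueError(f"edge ({u}, {v}) references unknown node")

    def to_networkx(self, reverse: bool = False) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for u, v in self.edges:
            if reverse:
                g.add_edge(v, u, sign=self.signs.get((u, v)))
            else:
                g.add_edge(u, v, sign=self.signs.get((u, v)))
        return g


def from_edges(edges, signs: dict | None = None, nodes=None) -> DirectedNetwork:
    """Build a DirectedNetwork from an edge iterable (nodes inferred)."""
    edges = list(edges)
    if nodes is None:
        nodes = sorted({u for u, _ in edges} | {v for _, v in edges})
    return DirectedNetwork(list(nodes), edges, dict(signs or {}))


def out_degree_hubs(net: DirectedNetwork, top_k: int | None = None) -> list[tuple[str, int]]:
    """Nodes ranked by number of predicted targets (descending,
    lexicographic tie-break)."""
    g = net.to_networkx()
    ranked = sorted(g.out_degree(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:top_k] if top_k is not None else ranked


def betweenness(net: DirectedNetwork) -> dict[str, float]:
    """Unnormalized directed betweenness centrality per node.

    b_i = sum over ordered pairs (j, k), j != k != i, of the fraction
    of shortest j->k paths passing through i (unweighted edges).
    """
    g = net.to_networkx()
    return dict(nx.betweenness_centrality(g, normalized=False))


def pagerank(
    net: DirectedNetwork,
    damping: float = 0.85,
    tol: float = 1e-10,
    direction: str = "reversed",
    max_iter: int = 10_000,
) -> dict[str, float]:
    """PageRank scores (summing to 1) with uniform teleport.

    ``direction='reversed'`` (default) ranks master regulators: edge
    direction regulator->target is flipped so that regulating a hub
    confers importance.  Dangling-node mass is redistributed uniformly.
    """
    if direction not in {"reversed", "forward"}:
        raise ValueError("direction must be 'reversed' or 'forward'")
    g = net.to_networkx(reverse=direction == "reversed")
    try:
        scores = nx.pagerank(g, alpha=damping, tol=tol, max_iter=max_iter)
    except nx.PowerIterationFailedConvergence as exc:
        raise RuntimeError(f"PageRank failed to converge in {max_iter} iterations") from exc
    return {str(k): float(v) for k, v in scores.items()}
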