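"""Integrated Herb-Compound-Target-Pathway (H-C-T-P) multipartite network.

Nodes carry one of four classes (herb, compound, target, pathway); edges are
only allowed between adjacent layers (herb-compound, compound-target,
target-pathway). Key components are the compounds of maximal degree, degree
counting incident edges from both neighbouring layers.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd

__all__ = ["NODE_CLASSES", "ComponentRanking", "build_hctp", "rank_by_degree"]

NODE_CLASSES = ("herb", "compound", "target", "pathway")

# allowed unordered class pairs
_ADJACENT = {frozenset(("herb", "compound")), frozenset(("compound", "target")), frozenset(("target", "pathway"))}


@dataclass
class ComponentRanking:
    """Degree ranking of one node class with the selected key set."""

    ranking: pd.DataFrame  # columns: node_id, degree (non-increasing)
    key_components: list[str]


def build_hctp(herb_compound, compound_target, target_pathway) -> nx.Graph:
    """Multipartite graph from the three inter-layer edge lists.

    Each argument is an iterable of id pairs whose positional classes are
    declared by the argument itself, e.g. ``herb_compound`` rows are
    ``(herb_id, compound_id)``. A node appearing with two different classes,
    or an edge within a layer, raises a structural error naming the culprit.
    """
    g = nx.Graph()

    def add(u, cu, v, cv):
        for node, cls in ((u, cu), (v, cv)):
            prev = g.nodes[node]["node_class"] if node in g else None
            if prev is not None and prev != cls:
                raise ValueError(f"node {node!r} declared both {prev!r} and {cls!r}")
            g.add_node(node, node_class=cls)
        if u == v:
            raise ValueError(f"self-edge on node {u!r}")
        if frozenset((cu, cv)) not in _ADJACENT:
            raise ValueError(f"edge ({u!r}, {v!r}) links non-adjacent classes {cu}-{cv}")
        g.add_edge(u, v)

    for h, c in herb_compound:
        add(h, "herb", c, "compound")
    for c, t in compound_target:
        add(c, "compound", t, "target")
    for t, p in target_pathway:
        add(t, "target", p, "pathway")
    return g


def class_counts(net: nx.Graph) -> dict[str, int]:
    """Node count per class (all four classes reported, possibly 0)."""
    out = {c: 0 for c in NODE_CLASSES}
    for _, cls in net.nodes(data="node_class"):
        out[cls] += 1
    return out


def rank_by_degree(net: nx.Graph, node_class: str = "compound", top="max-tie") -> ComponentRanking:
    """Rank one layer's nodes by degree over all incident edges.

    ``top="max-tie"`` selects every node sharing the maximal degree (the key
    components); an integer selects the top-k by the same ordering.
    """
    if node_class not in NODE_CLASSES:
        raise ValueError(f"unknown node class {node_class!r}; expected one of {NODE_CLASSES}")
    nodes = [n for n, c in net.nodes(data="node_class") if c == node_class]
    if not nodes:
        raise ValueError(f"network has no {node_class!r} nodes")
    df = pd.DataFrame({"node_id": nodes, "degree": [net.degree(n) for n in nodes]})
    df = df.sort_values(["degree", "node_id"], ascending=[False, True], kind="mergesort").reset_index(drop=True)
    if top == "max-tie":
        dmax = df["degree"].iloc[0]
        key = df.loc[df["degree"] == dmax, "node_id"].tolist()
    else:
        key = df.head(int(top))["node_id"].tolist()
    return ComponentRanking(ranking=df, key_components=key)
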