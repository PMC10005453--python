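"""Protein-protein interaction graph construction and topological analysis.

Builds an undirected simple graph of gene symbols from a confidence-scored
edge list (STRING-style), computes degree, shortest-path betweenness and
closeness centralities, selects key targets by conjunctive inclusive
thresholds, and recomputes centralities on the induced key-target subnetwork.

Conventions match Cytoscape's network analyzer: betweenness is normalised by
2/((n-1)(n-2)) with endpoints excluded; closeness is the reciprocal of the
mean shortest-path distance to *reachable* nodes (component-restricted),
0 for isolated nodes. A global Wasserman-Faust closeness is available via
``closeness="wf"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd

__all__ = [
    "KeyTargetCriteria",
    "build_graph",
    "centralities",
    "select_key_targets",
    "induced_subgraph_recompute",
    "edge_count_from_degrees",
]


@dataclass(frozen=True)
class KeyTargetCriteria:
    """Conjunctive inclusive thresholds for key-target selection."""

    min_degree: int = 10
    min_betweenness: float = 0.001
    min_closeness: float = 0.430

    def __post_init__(self):
        if self.min_degree < 0 or self.min_betweenness < 0 or self.min_closeness < 0:
            raise ValueError("key-target criteria must be non-negative")


def build_graph(edges, min_score: float = 0.7) -> nx.Graph:
    """Undirected simple graph from a scored edge list.

    Edges with score >= ``min_score`` are retained; self-loops are dropped;
    duplicate edges in either orientation collapse keeping the maximum score.

    Parameters
    ----------
    edges
        Iterable of ``(symbol, symbol, score)`` triples or a DataFrame with
        columns ``protein1, protein2, combined_score`` (scores on a 0-1 scale).
    """
    if isinstance(edges, pd.DataFrame):
        edges = edges[["protein1", "protein2", "combined_score"]].itertuples(index=False)
    g = nx.Graph()
    for i, row in enumerate(edges):
        try:
            u, v, score = row
            score = float(score)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"malformed edge row {i}: {row!r}") from exc
        if u == v or score < min_score:
            continue
        if g.has_edge(u, v):
            g[u][v]["score"] = max(g[u][v]["score"], score)
        else:
            g.add_edge(u, v, score=score)
    return g


def centralities(g: nx.Graph, closeness: str = "reachable") -> pd.DataFrame:
    """Degree, betweenness and closeness centrality for every node.

    Returns a DataFrame with columns ``gene_symbol, degree, betweenness,
    closeness``, sorted by descending degree then symbol.

    ``closeness="reachable"`` (default) is the component-restricted
    1 / mean-distance-to-reachable-nodes form; ``"wf"`` applies the
    Wasserman-Faust reachable-fraction scaling for disconnected graphs.
    """
    if g.number_of_nodes() == 0:
        return pd.DataFrame(columns=["gene_symbol", "degree", "betweenness", "closeness"])
    bet = nx.betweenness_centrality(g, normalized=True)
    if closeness == "reachable":
        clo = nx.closeness_centrality(g, wf_improved=False)
    elif closeness == "wf":
        clo = nx.closeness_centrality(g, wf_improved=True)
    else:
        raise ValueError(f"unknown closeness convention {closeness!r}")
    df = pd.DataFrame(
        {
            "gene_symbol": list(g.nodes),
            "degree": [g.degree(n) for n in g.nodes],
            "betweenness": [bet[n] for n in g.nodes],
            "closeness": [clo[n] for n in g.nodes],
        }
    )
    return df.sort_values(
        ["degree", "gene_symbol"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


def select_key_targets(records: pd.DataFrame, criteria: KeyTargetCriteria | None = None) -> list[str]:
    """Symbols meeting all three inclusive thresholds, in descending-degree order."""
    c = criteria or KeyTargetCriteria()
    hit = records[
        (records["degree"] >= c.min_degree)
        & (records["betweenness"] >= c.min_betweenness)
        & (records["closeness"] >= c.min_closeness)
    ]
    hit = hit.sort_values(["degree", "gene_symbol"], ascending=[False, True], kind="mergesort")
    return hit["gene_symbol"].tolist()


def induced_subgraph_recompute(
    g: nx.Graph, keep, closeness: str = "reachable"
) -> tuple[nx.Graph, pd.DataFrame]:
    """Induced subgraph on ``keep`` with centralities recomputed on it."""
    keep = list(keep)
    unknown = [s for s in keep if s not in g]
    if unknown:
        raise ValueError(f"symbols not in graph: {unknown}")
    sub = nx.Graph(g.subgraph(keep))
    return sub, centralities(sub, closeness=closeness)


def edge_count_from_degrees(degrees) -> int:
    """Edge count of a closed graph from its degree sequence (handshake lemma)."""
    total = int(sum(int(d) for d in degrees))
    if total % 2:
        raise ValueError(f"degree sum {total} is odd; not a closed graph's degree sequence")
    return total // 2
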