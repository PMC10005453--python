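import numpy as np
import pytest

from netpharm import StudyConfig, generate_study


@pytest.fixture(scope="session")
def default_bundle():
    """One default synthetic study bundle with its ground truth (seed 1)."""
    return generate_study(StudyConfig(seed=1))


# ---------------------------------------------------------------------------
# brute-force graph-centrality oracle (pure python, independent of networkx)
# ---------------------------------------------------------------------------

def _bfs_dist(adj, s):
    dist = {s: 0}
    frontier = [s]
    while frontier:
        nxt = []
        for u in frontier:
            for v in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    return dist


def _count_shortest_paths(adj, dist, s, t, via):
    """(total shortest s-t paths, those passing through `via`) by DFS on the BFS dag."""
    total = passing = 0
    stack = [(s, (s,))]
    while stack:
        u, path = stack.pop()
        if u == t:
            total += 1
            passing += via in path[1:-1]
            continue
        for v in adj[u]:
            if dist.get(v, -1) == dist[u] + 1 and dist.get(t, -1) >= dist[v]:
                stack.append((v, path + (v,)))
    return total, passing


def brute_force_centralities(adj):
    """Degree, normalized betweenness and component-restricted closeness for a
    graph given as an adjacency dict {node: set(neighbours)}."""
    nodes = sorted(adj)
    n = len(nodes)
    dists = {s: _bfs_dist(adj, s) for s in nodes}
    out = {}
    for v in nodes:
        deg = len(adj[v])
        reach = [d for u, d in dists[v].items() if u != v]
        clo = len(reach) / sum(reach) if reach and sum(reach) else 0.0
        bet = 0.0
        if n > 2:
            for i, s in enumerate(nodes):
                for t in nodes[i + 1:]:
                    if s == v or t == v or t not in dists[s]:
                        continue
                    total, passing = _count_shortest_paths(adj, dists[s], s, t, v)
                    if total:
                        bet += passing / total
            bet *= 2.0 / ((n - 1) * (n - 2))
        out[v] = (deg, bet, clo)
    return out


def random_adjacency(rng, n_max=8):
    """Random simple undirected graph (possibly disconnected, isolated nodes allowed)."""
    n = int(rng.integers(2, n_max + 1))
    adj = {i: set() for i in range(n)}
    p = rng.uniform(0.15, 0.7)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                adj[i].add(j)
                adj[j].add(i)
    return adj
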