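"""Independent oracles and graph builders shared across the test suite.

Everything here recomputes quantities from first principles (BFS distance
tables, all-pairs path counting, exhaustive subset enumeration) so that the
package's own implementations are checked against a different algorithm,
not against themselves.
"""

from collections import deque
from itertools import combinations
from math import comb

import numpy as np

from cernanet.network import CeRNANetwork


def random_tripartite_net(rng, max_side=10, p_edge=0.3) -> CeRNANetwork:
    """A random lncRNA/miRNA/mRNA graph, possibly disconnected."""
    nl = int(rng.integers(1, max_side + 1))
    nm = int(rng.integers(1, max_side + 1))
    nr = int(rng.integers(1, max_side + 1))
    lnc = [f"L{i}" for i in range(nl)]
    mir = [f"M{i}" for i in range(nm)]
    mrna = [f"G{i}" for i in range(nr)]
    edges = set()
    for a in lnc:
        for b in mir:
            if rng.random() < p_edge:
                edges.add((a, b) if a <= b else (b, a))
    for a in mir:
        for b in mrna:
            if rng.random() < p_edge:
                edges.add((a, b) if a <= b else (b, a))
    return CeRNANetwork(
        lnc_nodes=set(lnc), mi_nodes=set(mir), mrna_nodes=set(mrna), edges=edges
    )


def path_net(*chain) -> CeRNANetwork:
    """A path graph with alternating lncRNA/miRNA classes (classes unused
    by the centrality math)."""
    edges = {tuple(sorted(e)) for e in zip(chain, chain[1:])}
    return CeRNANetwork(
        lnc_nodes=set(chain[0::2]), mi_nodes=set(chain[1::2]),
        mrna_nodes=set(), edges=edges,
    )


def bfs_all(net):
    """Distance and shortest-path-count tables from every source."""
    adj = net.adjacency()
    nodes = net.nodes
    dist, sigma = {}, {}
    for s in nodes:
        d = {s: 0}
        c = {s: 1}
        q = deque([s])
        while q:
            v = q.popleft()
            for w in adj[v]:
                if w not in d:
                    d[w] = d[v] + 1
                    c[w] = 0
                    q.append(w)
                if d[w] == d[v] + 1:
                    c[w] += c[v]
        dist[s] = d
        sigma[s] = c
    return dist, sigma


def brute_degree(net) -> dict:
    nodes = net.nodes
    deg = {v: 0 for v in nodes}
    for a, b in net.edges:
        deg[a] += 1
        deg[b] += 1
    return deg


def brute_closeness(net) -> dict:
    """Component-scoped closeness with whole-graph (c-1)/(n-1) scaling."""
    dist, _ = bfs_all(net)
    n = net.n_nodes
    out = {}
    for v in net.nodes:
        reach = dist[v]
        c = len(reach)
        tot = sum(reach.values())
        out[v] = 0.0 if (n <= 1 or c <= 1) else ((c - 1) / tot) * ((c - 1) / (n - 1))
    return out


def brute_betweenness_raw(net) -> dict:
    """All-pairs combination-formula betweenness (not Brandes).

    For every unordered pair (s, t) and candidate intermediate v, the
    fraction of shortest s-t paths through v is
    sigma(s,v)*sigma(v,t)/sigma(s,t) when d(s,v)+d(v,t)=d(s,t).
    """
    dist, sigma = bfs_all(net)
    nodes = net.nodes
    bet = {v: 0.0 for v in nodes}
    for s, t in combinations(nodes, 2):
        if t not in dist[s]:
            continue
        dst = dist[s][t]
        for v in nodes:
            if v in (s, t):
                continue
            if v in dist[s] and t in dist[v]:
                if dist[s][v] + dist[v][t] == dst:
                    bet[v] += sigma[s][v] * sigma[v][t] / sigma[s][t]
    return bet


def brute_betweenness(net) -> dict:
    raw = brute_betweenness_raw(net)
    n = net.n_nodes
    denom = (n - 1) * (n - 2) / 2
    return {v: (b / denom if denom > 0 else 0.0) for v, b in raw.items()}


def total_intermediate_visits(net) -> float:
    """Sum over connected pairs of (d(s,t) - 1): the expected number of
    intermediate vertices on a shortest path, accumulated over all pairs."""
    dist, _ = bfs_all(net)
    total = 0.0
    for s, t in combinations(net.nodes, 2):
        if t in dist[s]:
            total += max(dist[s][t] - 1, 0)
    return total


def hypergeom_upper_tail_enum(k, K, n, N) -> float:
    """P[X >= k] by exhaustive enumeration of all K-subsets of the universe."""
    universe = list(range(N))
    annotated = set(range(n))
    hits = 0
    total = comb(N, K)
    for subset in combinations(universe, K):
        if len(annotated.intersection(subset)) >= k:
            hits += 1
    return hits / total


def bh_stepup_reference(p) -> np.ndarray:
    """Literal step-up BH: find the largest i with p_(i) <= i*alpha/m by
    scanning from the bottom; expressed as adjusted values."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        val = min(prev, p[idx] * m / rank)
        adj[idx] = val
        prev = val
    return np.clip(adj, 0, 1)
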