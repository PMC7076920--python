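"""Tripartite ceRNA network assembly, centrality analysis, and hub calling.

The network joins three node classes — lncRNA, miRNA, mRNA — through two
bipartite edge sets (lncRNA-miRNA and miRNA-mRNA) and is analyzed as one
undirected simple graph.  Hubs are the nodes ranked in the top k
(default 40) simultaneously for degree, closeness, and betweenness
centrality.

Centralities are computed from first principles (BFS shortest paths and
Brandes' dependency accumulation) under the conventions standard in network
analysis tools:

* degree — raw edge count (unnormalized integers);
* closeness — component-scoped: for node v in a connected component of size
  c inside a graph of n nodes, (c-1)/sum(d(v,u)) scaled by (c-1)/(n-1);
  the alternative harmonic closeness is available via ``mode="harmonic"``;
* betweenness — sum of fractional pair-dependencies over all shortest paths,
  endpoints excluded, normalized by (n-1)(n-2)/2.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ContractError, EmptyNetworkError
from .interactions import InteractionTable

NODE_CLASSES = ("lncRNA", "miRNA", "mRNA")


# ---------------------------------------------------------------------------
# Graph container
# ---------------------------------------------------------------------------

@dataclass
class CeRNANetwork:
    """Undirected simple tripartite graph.

    Edges run only lncRNA-miRNA or miRNA-mRNA; after assembly every miRNA
    has at least one neighbor on each side and no node is isolated.
    """

    lnc_nodes: set = field(default_factory=set)
    mi_nodes: set = field(default_factory=set)
    mrna_nodes: set = field(default_factory=set)
    edges: set = field(default_factory=set)  # frozenset-style sorted 2-tuples

    @property
    def nodes(self) -> list:
        return sorted(self.lnc_nodes) + sorted(self.mi_nodes) + sorted(self.mrna_nodes)

    @property
    def n_nodes(self) -> int:
        return len(self.lnc_nodes) + len(self.mi_nodes) + len(self.mrna_nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def node_class(self, node) -> str:
        if node in self.lnc_nodes:
            return "lncRNA"
        if node in self.mi_nodes:
            return "miRNA"
        if node in self.mrna_nodes:
            return "mRNA"
        raise KeyError(node)

    def adjacency(self) -> dict:
        adj: dict[str, set] = {v: set() for v in self.nodes}
        for a, b in self.edges:
            adj[a].add(b)
            adj[b].add(a)
        return adj


def _edge(a, b) -> tuple:
    return (a, b) if a <= b else (b, a)


def assemble(lnc_mi_de: InteractionTable, mi_mrna_de: InteractionTable) -> CeRNANetwork:
    """Build the tripartite graph and prune it to the ceRNA-competent core.

    A miRNA participates in a ceRNA relationship only if it bridges a lncRNA
    and an mRNA, so miRNAs lacking a partner on either side are removed with
    their edges; lncRNAs/mRNAs left without any edge are then dropped.
    """
    if not lnc_mi_de.pairs and not mi_mrna_de.pairs:
        raise EmptyNetworkError(
            "no lncRNA-miRNA and no miRNA-mRNA pairs survive the DE filter; "
            "nothing to assemble"
        )
    lnc_partners: dict[str, set] = {}
    mrna_partners: dict[str, set] = {}
    for lnc, mi in lnc_mi_de.pairs:
        lnc_partners.setdefault(mi, set()).add(lnc)
    for mi, mrna in mi_mrna_de.pairs:
        mrna_partners.setdefault(mi, set()).add(mrna)

    keep_mi = {
        mi for mi in set(lnc_partners) & set(mrna_partners)
        if lnc_partners[mi] and mrna_partners[mi]
    }
    if not keep_mi:
        raise EmptyNetworkError(
            "no miRNA has both a lncRNA partner and an mRNA target; "
            "the ceRNA network is empty"
        )
    net = CeRNANetwork()
    net.mi_nodes = keep_mi
    for mi in keep_mi:
        for lnc in lnc_partners[mi]:
            net.lnc_nodes.add(lnc)
            net.edges.add(_edge(lnc, mi))
        for mrna in mrna_partners[mi]:
            net.mrna_nodes.add(mrna)
            net.edges.add(_edge(mi, mrna))
    return net


# ---------------------------------------------------------------------------
# Centralities
# ---------------------------------------------------------------------------

def _bfs_distances(adj: dict, source) -> dict:
    dist = {source: 0}
    q = deque([source])
    while q:
        v = q.popleft()
        for w in adj[v]:
            if w not in dist:
                dist[w] = dist[v] + 1
                q.append(w)
    return dist


def degree_centrality(net: CeRNANetwork) -> dict:
    """Raw degree: the number of edges incident to each node."""
    deg = {v: 0 for v in net.nodes}
    for a, b in net.edges:
        deg[a] += 1
        deg[b] += 1
    return deg


def closeness_centrality(net: CeRNANetwork, mode: str = "component") -> dict:
    """Closeness centrality in [0, 1], defined on disconnected graphs.

    ``mode="component"`` (default): (c-1)/sum_dist within the component,
    scaled by (c-1)/(n-1).  ``mode="harmonic"``: sum of reciprocal distances
    to all other nodes divided by (n-1).
    """
    if mode not in ("component", "harmonic"):
        raise ContractError(f"unknown closeness mode '{mode}'")
    adj = net.adjacency()
    n = net.n_nodes
    out = {}
    for v in net.nodes:
        dist = _bfs_distances(adj, v)
        if n <= 1:
            out[v] = 0.0
            continue
        if mode == "harmonic":
            out[v] = sum(1.0 / d for d in dist.values() if d > 0) / (n - 1)
            continue
        c = len(dist)  # component size
        total = sum(dist.values())
        if c <= 1 or total == 0:
            out[v] = 0.0
        else:
            out[v] = ((c - 1) / total) * ((c - 1) / (n - 1))
    return out


def betweenness_centrality(net: CeRNANetwork) -> dict:
    """Shortest-path betweenness by Brandes' accumulation, normalized.

    Equally short paths share credit fractionally; endpoints are excluded;
    raw values are divided by (n-1)(n-2)/2 pairs for the undirected graph.
    """
    raw = betweenness_raw(net)
    n = net.n_nodes
    denom = (n - 1) * (n - 2) / 2.0
    if denom <= 0:
        return {v: 0.0 for v in raw}
    return {v: b / denom for v, b in raw.items()}


def betweenness_raw(net: CeRNANetwork) -> dict:
    """Unnormalized betweenness: expected shortest-path traffic per node."""
    adj = net.adjacency()
    nodes = net.nodes
    bet = dict.fromkeys(nodes, 0.0)
    for s in nodes:
        # single-source shortest paths with path counting
        stack: list = []
        pred: dict = {v: [] for v in nodes}
        sigma = dict.fromkeys(nodes, 0.0)
        sigma[s] = 1.0
        dist = dict.fromkeys(nodes, -1)
        dist[s] = 0
        q = deque([s])
        while q:
            v = q.popleft()
            stack.append(v)
            for w in adj[v]:
                if dist[w] < 0:
                    dist[w] = dist[v] + 1
                    q.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
                    pred[w].append(v)
        delta = dict.fromkeys(nodes, 0.0)
        while stack:
            w = stack.pop()
            for v in pred[w]:
                delta[v] += (sigma[v] / sigma[w]) * (1.0 + delta[w])
            if w != s:
                bet[w] += delta[w]
    # each unordered pair was counted from both endpoints
    return {v: b / 2.0 for v, b in bet.items()}


def centrality_table(net: CeRNANetwork, closeness_mode: str = "component") -> pd.DataFrame:
    """Per-node record of class and the three centralities."""
    deg = degree_centrality(net)
    clo = closeness_centrality(net, mode=closeness_mode)
    bet = betweenness_centrality(net)
    rows = [
        {
            "node_id": v,
            "node_class": net.node_class(v),
            "degree": deg[v],
            "closeness": clo[v],
            "betweenness": bet[v],
        }
        for v in net.nodes
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Kruskal-Wallis comparison across node classes
# ---------------------------------------------------------------------------

def kruskal_wallis(groups) -> tuple[float, float]:
    """Kruskal-Wallis H with tie correction; p from chi-square(k-1).

    All-tied data gives H = 0 (the 0/0 case resolves to no separation).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ContractError("need >=2 non-empty groups for Kruskal-Wallis")
    pooled = np.concatenate(groups)
    n_total = len(pooled)
    ranks = sps.rankdata(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start:start + len(g)]
        start += len(g)
        h += len(g) * (r.mean() - (n_total + 1) / 2.0) ** 2
    h *= 12.0 / (n_total * (n_total + 1))
    # tie correction
    _, counts = np.unique(pooled, return_counts=True)
    tie_sum = float(np.sum(counts.astype(float) ** 3 - counts))
    denom = 1.0 - tie_sum / (n_total**3 - n_total)
    if denom == 0.0:
        return 0.0, 1.0
    h /= denom
    p = float(sps.chi2.sf(h, len(groups) - 1))
    return float(h), p


def compare_centrality_by_class(records: pd.DataFrame) -> dict:
    """Kruskal-Wallis test of each centrality across the node classes."""
    classes = [c for c in NODE_CLASSES if (records["node_class"] == c).any()]
    if len(classes) < 2:
        raise ContractError("need at least two node classes to compare")
    out = {}
    for metric in ("degree", "closeness", "betweenness"):
        groups = [
            records.loc[records["node_class"] == c, metric].to_numpy(float)
            for c in classes
        ]
        out[metric] = kruskal_wallis(groups)
    return out


# ---------------------------------------------------------------------------
# Hub calling
# ---------------------------------------------------------------------------

@dataclass
class HubSet:
    """Triple-consensus hubs: nodes in the top k for all three centralities."""

    hubs: set
    k: int
    per_metric_topk: dict  # metric -> node id set


def _top_k_with_ties(records: pd.DataFrame, metric: str, k: int) -> set:
    vals = records[metric].to_numpy()
    if len(vals) <= k:
        return set(records["node_id"])
    cutoff = np.sort(vals)[::-1][k - 1]
    return set(records.loc[records[metric] >= cutoff, "node_id"])


def consensus_hubs(records: pd.DataFrame, k: int = 40) -> HubSet:
    """Intersect the tie-inclusive top-k node sets of the three centralities.

    Competition ranking: every node tied with the k-th ranked value is kept,
    so the per-metric sets can exceed k but never depend on input order.
    """
    if records.empty:
        raise ContractError("no centrality records; cannot call hubs")
    if k < 1:
        raise ContractError(f"k must be >= 1, got {k}")
    per_metric = {
        metric: _top_k_with_ties(records, metric, k)
        for metric in ("degree", "closeness", "betweenness")
    }
    hubs = per_metric["degree"] & per_metric["closeness"] & per_metric["betweenness"]
    return HubSet(hubs=hubs, k=k, per_metric_topk=per_metric)


# ---------------------------------------------------------------------------
# Exports
# ---------------------------------------------------------------------------

def write_sif(net: CeRNANetwork, path) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(net.edges):
            rel = "lnc-mi" if a in net.lnc_nodes or b in net.lnc_nodes else "mi-mrna"
            fh.write(f"{a}\t{rel}\t{b}\n")


def write_graphml(net: CeRNANetwork, path) -> None:
    """Minimal GraphML export with a node_class attribute."""
    import xml.etree.ElementTree as ET

    root = ET.Element(
        "graphml", xmlns="http://graphml.graphdrawing.org/xmlns"
    )
    key = ET.SubElement(root, "key")
    key.set("id", "d0")
    key.set("for", "node")
    key.set("attr.name", "node_class")
    key.set("attr.type", "string")
    graph = ET.SubElement(root, "graph", edgedefault="undirected")
    for v in net.nodes:
        node = ET.SubElement(graph, "node", id=v)
        data = ET.SubElement(node, "data", key="d0")
        data.text = net.node_class(v)
    for a, b in sorted(net.edges):
        ET.SubElement(graph, "edge", source=a, target=b)
    ET.ElementTree(root).write(path, xml_declaration=True, encoding="unicode")


def write_centrality_table(records: pd.DataFrame, path) -> None:
    cols = ["node_id", "node_class", "closeness", "degree", "betweenness"]
    records[cols].to_csv(path, sep="\t", index=False)


def write_hubs(hubset: HubSet, records: pd.DataFrame, path) -> None:
    rows = records[records["node_id"].isin(hubset.hubs)].sort_values(
        ["node_class", "closeness"], ascending=[True, False]
    )
    write_centrality_table(rows, path)
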