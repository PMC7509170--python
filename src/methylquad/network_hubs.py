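"""Dense-module detection and multi-centrality hub ranking on PPI graphs.

Module detection reimplements the Molecular Complex Detection (MCODE)
procedure: vertices are weighted by the density of the highest k-core of
their closed neighborhood times the core number, complexes grow greedily
from top-weighted seeds admitting neighbors whose weight stays within a
fraction of the seed weight, and candidate complexes are post-filtered by
a 2-core requirement (haircut). A module's score is its density times its
node count; significant modules need score > 3 and more than 4 nodes.

Hub ranking computes twelve topological scores per node — Degree, MCC,
MNC, DMNC, EPC, BottleNeck, EcCentricity, Closeness, Radiality,
Betweenness, Stress and ClusteringCoefficient — and aggregates them into
a comprehensive standard by summing per-algorithm ranks (average ranks on
ties). The definitions follow the published cytoHubba descriptions and
are documented reconstructions; edge weights play no role in the scores.
"""
from __future__ import annotations

import logging
import math
from collections import deque
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ALGORITHMS = (
    "Degree",
    "MCC",
    "MNC",
    "DMNC",
    "EPC",
    "BottleNeck",
    "EcCentricity",
    "Closeness",
    "Radiality",
    "Betweenness",
    "Stress",
    "ClusteringCoefficient",
)

DMNC_EPSILON = 1.7
#: maximal-clique enumeration budget before MCC falls back to degree
MCC_CLIQUE_BUDGET = 500_000


@dataclass(frozen=True)
class ModuleResult:
    """A detected dense module."""

    nodes: tuple[str, ...]
    score: float
    seed: str

    @property
    def size(self) -> int:
        return len(self.nodes)


def _density(g: nx.Graph) -> float:
    n = g.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * g.number_of_edges() / (n * (n - 1))


def _vertex_weights(graph: nx.Graph) -> dict:
    """MCODE vertex weighting: core number x density of the highest
    k-core of the closed neighborhood."""
    weights = {}
    for v in graph:
        nbhd = set(graph[v]) | {v}
        sub = graph.subgraph(nbhd)
        core = nx.core_number(sub)
        k = max(core.values())
        kcore = sub.subgraph([u for u, c in core.items() if c >= k])
        weights[v] = k * _density(kcore)
    return weights


def mcode_modules(
    graph: nx.Graph,
    node_score_cutoff: float = 0.2,
    k_core: int = 2,
    haircut: bool = True,
    fluff: bool = False,
    min_score: float = 3.0,
    min_nodes: int = 5,
) -> list[ModuleResult]:
    """MCODE-style dense-module detection.

    Returns modules with score strictly greater than ``min_score`` and at
    least ``min_nodes`` nodes, sorted by descending score (ties: larger
    module, then seed symbol).
    """
    if graph.number_of_nodes() == 0:
        return []
    weights = _vertex_weights(graph)
    order = sorted(graph.nodes, key=lambda v: (-weights[v], str(v)))
    assigned: set = set()
    raw: list[tuple[set, str]] = []
    for seed in order:
        if seed in assigned:
            continue
        threshold = weights[seed] * (1.0 - node_score_cutoff)
        members = {seed}
        queue = deque([seed])
        while queue:
            u = queue.popleft()
            for nbr in graph[u]:
                if nbr in members or nbr in assigned:
                    continue
                if weights[nbr] > threshold:
                    members.add(nbr)
                    queue.append(nbr)
        assigned |= members
        raw.append((members, seed))

    modules = []
    for members, seed in raw:
        sub = graph.subgraph(members)
        core = nx.k_core(sub, k_core)
        if core.number_of_nodes() == 0:
            continue
        final = core if haircut else sub
        if fluff:
            extra = {
                nbr
                for v in final
                for nbr in graph[v]
                if nbr not in assigned or nbr in members
            }
            final = graph.subgraph(set(final) | extra)
        score = _density(final) * final.number_of_nodes()
        if score > min_score and final.number_of_nodes() >= min_nodes:
            modules.append(
                ModuleResult(tuple(sorted(final.nodes)), float(score), seed)
            )
    modules.sort(key=lambda m: (-m.score, -m.size, m.seed))
    return modules


def top_modules(modules: list[ModuleResult], k: int = 3) -> list[ModuleResult]:
    return modules[:k]


# ---------------------------------------------------------------------------
# the twelve hub scores
# ---------------------------------------------------------------------------

def _bfs_paths(graph: nx.Graph, source) -> tuple[dict, dict]:
    """Distances and shortest-path counts from ``source`` (unweighted)."""
    dist = {source: 0}
    sigma = {source: 1.0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for w in graph[u]:
            if w not in dist:
                dist[w] = dist[u] + 1
                sigma[w] = 0.0
                queue.append(w)
            if dist[w] == dist[u] + 1:
                sigma[w] += sigma[u]
    return dist, sigma


def _stress(graph: nx.Graph) -> dict:
    """Stress centrality: number of shortest paths passing through a node."""
    nodes = list(graph.nodes)
    dist = {}
    sigma = {}
    for s in nodes:
        dist[s], sigma[s] = _bfs_paths(graph, s)
    stress = {v: 0.0 for v in nodes}
    for i, s in enumerate(nodes):
        for t in nodes[i + 1 :]:
            if t not in dist[s]:
                continue
            d_st = dist[s][t]
            for v in nodes:
                if v == s or v == t or v not in dist[s] or v not in dist[t]:
                    continue
                if dist[s][v] + dist[t][v] == d_st:
                    stress[v] += sigma[s][v] * sigma[t][v]
    return stress


def _bottleneck(graph: nx.Graph) -> dict:
    """BottleNeck score: for each root's shortest-path tree, nodes whose
    subtree carries more than a quarter of the reachable nodes are
    bottlenecks; the score counts the trees in which a node qualifies.
    Parents are the lexicographically smallest shortest-path predecessor,
    making the tree deterministic."""
    score = {v: 0.0 for v in graph}
    for root in graph:
        dist, _ = _bfs_paths(graph, root)
        reachable = sorted(dist, key=lambda v: (dist[v], str(v)))
        parent = {}
        for v in reachable:
            if v == root:
                continue
            preds = [u for u in graph[v] if u in dist and dist[u] == dist[v] - 1]
            parent[v] = min(preds, key=str)
        subtree = {v: 1 for v in reachable}
        for v in reversed(reachable):
            if v != root:
                subtree[parent[v]] += subtree[v]
        n = len(reachable)
        for v in reachable:
            if v != root and subtree[v] > n / 4.0:
                score[v] += 1.0
    return score


def _mcc(graph: nx.Graph) -> dict:
    """Maximal Clique Centrality: sum over maximal cliques containing the
    node of (clique size - 1)!. Falls back to degree if clique
    enumeration exceeds the budget."""
    mcc = {v: 0.0 for v in graph}
    count = 0
    try:
        for clique in nx.find_cliques(graph):
            count += 1
            if count > MCC_CLIQUE_BUDGET:
                raise OverflowError
            w = math.factorial(len(clique) - 1)
            for v in clique:
                mcc[v] += w
    except OverflowError:
        logger.warning(
            "clique enumeration exceeded budget (%d); MCC falls back to degree",
            MCC_CLIQUE_BUDGET,
        )
        return {v: float(graph.degree(v)) for v in graph}
    return mcc


def _neighborhood_component(graph: nx.Graph, v) -> nx.Graph:
    """Largest connected component of the open neighborhood of ``v``."""
    sub = graph.subgraph(list(graph[v]))
    if sub.number_of_nodes() == 0:
        return sub
    comp = max(nx.connected_components(sub), key=lambda c: (len(c), sorted(map(str, c))))
    return sub.subgraph(comp)


def _epc(graph: nx.Graph, rounds: int, retention: float, rng: np.random.Generator) -> dict:
    """Edge Percolated Component: mean size of the component containing
    the node after retaining each edge independently with probability
    ``retention``, over ``rounds`` random rounds."""
    nodes = list(graph.nodes)
    edges = list(graph.edges)
    acc = {v: 0.0 for v in nodes}
    for _ in range(rounds):
        keep = rng.random(len(edges)) < retention
        g = nx.Graph()
        g.add_nodes_from(nodes)
        g.add_edges_from(e for e, k in zip(edges, keep) if k)
        for comp in nx.connected_components(g):
            size = len(comp)
            for v in comp:
                acc[v] += size
    return {v: acc[v] / rounds for v in nodes}


def centrality_scores(
    graph: nx.Graph,
    epc_rounds: int = 1000,
    epc_retention: float = 0.5,
    seed: int | None = 0,
) -> pd.DataFrame:
    """All twelve hub scores on the unweighted topology.

    Shortest-path scores are computed within connected components;
    Closeness is the harmonic form (sum of reciprocal distances), which
    is well defined on disconnected graphs. EcCentricity is the
    reciprocal of the node's eccentricity in its component. Radiality
    uses the component diameter. EPC is stochastic and seeded.
    """
    if graph.number_of_nodes() < 2:
        raise ValueError("centrality scores need a graph with >= 2 nodes")
    nodes = sorted(graph.nodes, key=str)
    rng = np.random.default_rng(seed)

    degree = {v: float(graph.degree(v)) for v in nodes}
    mcc = _mcc(graph)
    clustering = nx.clustering(graph)
    betweenness = nx.betweenness_centrality(graph, normalized=False)
    stress = _stress(graph)
    bottleneck = _bottleneck(graph)
    epc = _epc(graph, epc_rounds, epc_retention, rng)

    mnc, dmnc = {}, {}
    for v in nodes:
        comp = _neighborhood_component(graph, v)
        n = comp.number_of_nodes()
        mnc[v] = float(n)
        dmnc[v] = comp.number_of_edges() / n**DMNC_EPSILON if n > 0 else 0.0

    closeness, eccentricity, radiality = {}, {}, {}
    for component in nx.connected_components(graph):
        sub = graph.subgraph(component)
        if len(component) == 1:
            (v,) = component
            closeness[v] = 0.0
            eccentricity[v] = 0.0
            radiality[v] = 0.0
            continue
        lengths = dict(nx.all_pairs_shortest_path_length(sub))
        diam = max(max(d.values()) for d in lengths.values())
        n = len(component)
        for v in component:
            dists = [d for u, d in lengths[v].items() if u != v]
            closeness[v] = sum(1.0 / d for d in dists)
            ecc = max(dists)
            eccentricity[v] = 1.0 / ecc
            radiality[v] = sum(diam + 1 - d for d in dists) / (n - 1)

    table = pd.DataFrame(
        {
            "Degree": degree,
            "MCC": mcc,
            "MNC": mnc,
            "DMNC": dmnc,
            "EPC": epc,
            "BottleNeck": bottleneck,
            "EcCentricity": eccentricity,
            "Closeness": closeness,
            "Radiality": radiality,
            "Betweenness": betweenness,
            "Stress": stress,
            "ClusteringCoefficient": clustering,
        },
        index=pd.Index(nodes, name="node"),
    )
    return table[list(ALGORITHMS)]


def aggregate_hubs(
    table: pd.DataFrame, top_k: int = 10, method: str = "rank_sum"
) -> pd.DataFrame:
    """Aggregate the twelve scores into a comprehensive hub ordering.

    ``rank_sum`` (default) ranks each algorithm's scores descending with
    average ranks on ties and sums the ranks; smaller is better.
    ``score_sum`` instead sums the raw scores (larger is better). Ties in
    the aggregate are broken by Degree (descending) then node symbol.
    Returns the full table with per-algorithm ranks, the aggregate and
    the final ordering; the first ``top_k`` rows are the hub list.
    """
    if method not in ("rank_sum", "score_sum"):
        raise ValueError(f"unknown aggregation method {method!r}")
    ranks = table.rank(ascending=False, method="average")
    out = table.copy()
    for col in table.columns:
        out[f"rank_{col}"] = ranks[col]
    if method == "rank_sum":
        out["aggregate_rank"] = ranks.sum(axis=1)
        sort_keys = ["aggregate_rank", "neg_degree", "node_key"]
        ascending = [True, True, True]
    else:
        out["aggregate_score"] = table.sum(axis=1)
        out["aggregate_rank"] = -out["aggregate_score"]
        sort_keys = ["aggregate_rank", "neg_degree", "node_key"]
        ascending = [True, True, True]
    out["neg_degree"] = -out["Degree"]
    out["node_key"] = out.index.astype(str)
    out = out.sort_values(sort_keys, ascending=ascending).drop(
        columns=["neg_degree", "node_key"]
    )
    out["final_rank"] = np.arange(1, len(out) + 1)
    return out


def top_hubs(table: pd.DataFrame, top_k: int = 10, method: str = "rank_sum") -> list[str]:
    ordered = aggregate_hubs(table, top_k=top_k, method=method)
    return list(ordered.index[:top_k])
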