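"""Independent brute-force oracles used by the test suite.

Everything here works directly on node/edge lists with exhaustive
enumeration (all simple paths, all subsets) and shares no code with the
package implementation.
"""
from __future__ import annotations

import itertools
import math


def adjacency(nodes, edges):
    adj = {v: set() for v in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    return adj


def all_simple_paths(adj, s, t):
    paths = []

    def dfs(path):
        u = path[-1]
        if u == t:
            paths.append(list(path))
            return
        for w in sorted(adj[u], key=str):
            if w not in path:
                path.append(w)
                dfs(path)
                path.pop()

    dfs([s])
    return paths


def shortest_path_data(nodes, edges):
    """For every ordered pair: distance and the set of shortest paths."""
    adj = adjacency(nodes, edges)
    dist = {}
    spaths = {}
    for s, t in itertools.combinations(nodes, 2):
        paths = all_simple_paths(adj, s, t)
        if not paths:
            continue
        d = min(len(p) for p in paths) - 1
        short = [p for p in paths if len(p) - 1 == d]
        dist[(s, t)] = dist[(t, s)] = d
        spaths[(s, t)] = short
    return dist, spaths


def maximal_cliques(nodes, edges):
    edge_set = {frozenset(e) for e in edges}

    def is_clique(sub):
        return all(frozenset((a, b)) in edge_set for a, b in itertools.combinations(sub, 2))

    cliques = [
        set(sub)
        for r in range(1, len(nodes) + 1)
        for sub in itertools.combinations(nodes, r)
        if is_clique(sub)
    ]
    return [c for c in cliques if not any(c < d for d in cliques)]


def components(nodes, edges):
    adj = adjacency(nodes, edges)
    seen, comps = set(), []
    for v in nodes:
        if v in seen:
            continue
        comp, stack = set(), [v]
        while stack:
            u = stack.pop()
            if u in comp:
                continue
            comp.add(u)
            stack.extend(adj[u] - comp)
        seen |= comp
        comps.append(comp)
    return comps


def brute_centralities(nodes, edges, dmnc_eps=1.7):
    """The eleven deterministic hub scores by exhaustive enumeration."""
    nodes = list(nodes)
    adj = adjacency(nodes, edges)
    dist, spaths = shortest_path_data(nodes, edges)
    comps = components(nodes, edges)
    comp_of = {v: c for c in comps for v in c}

    degree = {v: float(len(adj[v])) for v in nodes}

    mcc = {v: 0.0 for v in nodes}
    for clique in maximal_cliques(nodes, edges):
        w = math.factorial(len(clique) - 1)
        for v in clique:
            mcc[v] += w

    mnc, dmnc = {}, {}
    for v in nodes:
        nbrs = sorted(adj[v], key=str)
        sub_edges = [(a, b) for a, b in edges if a in adj[v] and b in adj[v]]
        if not nbrs:
            mnc[v], dmnc[v] = 0.0, 0.0
            continue
        comps_n = components(nbrs, sub_edges)
        big = max(comps_n, key=lambda c: (len(c), sorted(map(str, c))))
        n = len(big)
        m = sum(1 for a, b in sub_edges if a in big and b in big)
        mnc[v] = float(n)
        dmnc[v] = m / n**dmnc_eps

    clustering = {}
    for v in nodes:
        k = len(adj[v])
        if k < 2:
            clustering[v] = 0.0
            continue
        links = sum(
            1 for a, b in itertools.combinations(sorted(adj[v], key=str), 2) if b in adj[a]
        )
        clustering[v] = 2.0 * links / (k * (k - 1))

    betweenness = {v: 0.0 for v in nodes}
    stress = {v: 0.0 for v in nodes}
    for (s, t), paths in spaths.items():
        sigma = len(paths)
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            if through:
                betweenness[v] += through / sigma
                stress[v] += through

    closeness, eccentricity, radiality = {}, {}, {}
    for v in nodes:
        others = [u for u in comp_of[v] if u != v]
        if not others:
            closeness[v] = eccentricity[v] = radiality[v] = 0.0
            continue
        dists = [dist[(v, u)] for u in others]
        closeness[v] = sum(1.0 / d for d in dists)
        eccentricity[v] = 1.0 / max(dists)
        comp = comp_of[v]
        diam = max(
            dist[(a, b)] for a, b in itertools.combinations(sorted(comp, key=str), 2)
        )
        radiality[v] = sum(diam + 1 - d for d in dists) / (len(comp) - 1)

    bottleneck = {v: 0.0 for v in nodes}
    for root in nodes:
        reach = [v for v in nodes if v == root or (root, v) in dist]
        parent = {}
        for v in reach:
            if v == root:
                continue
            preds = [
                u
                for u in adj[v]
                if u in reach and (dist[(root, u)] if u != root else 0) == dist[(root, v)] - 1
            ]
            parent[v] = min(preds, key=str)
        size = {v: 1 for v in reach}
        for v in sorted(
            (u for u in reach if u != root),
            key=lambda u: -dist[(root, u)],
        ):
            size[parent[v]] += size[v]
        for v in reach:
            if v != root and size[v] > len(reach) / 4.0:
                bottleneck[v] += 1.0
    return {
        "Degree": degree,
        "MCC": mcc,
        "MNC": mnc,
        "DMNC": dmnc,
        "BottleNeck": bottleneck,
        "EcCentricity": eccentricity,
        "Closeness": closeness,
        "Radiality": radiality,
        "Betweenness": betweenness,
        "Stress": stress,
        "ClusteringCoefficient": clustering,
    }


def epc_exact(nodes, edges, retention):
    """Exact expectation and variance of the percolated-component size
    per node, by enumerating every edge subset."""
    nodes = list(nodes)
    edges = list(edges)
    m = len(edges)
    mean = {v: 0.0 for v in nodes}
    second = {v: 0.0 for v in nodes}
    for mask in range(2**m):
        kept = [edges[i] for i in range(m) if mask >> i & 1]
        k = len(kept)
        w = retention**k * (1 - retention) ** (m - k)
        for comp in components(nodes, kept):
            size = len(comp)
            for v in comp:
                mean[v] += w * size
                second[v] += w * size * size
    var = {v: second[v] - mean[v] ** 2 for v in nodes}
    return mean, var


def hypergeom_enumeration(N, K, n, k):
    """P(overlap >= k) by direct summation of counting ratios."""
    total = math.comb(N, n)
    return sum(math.comb(K, j) * math.comb(N - K, n - j) for j in range(k, min(K, n) + 1)) / total


def fisher_exact_2x2(table):
    """Two-sided Fisher p for a 2x2 table by exhaustive enumeration of
    tables with the same margins, summing probabilities <= observed."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(x):
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )

    p_obs = prob(a)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))


def welch_p(a, b):
    """Textbook Welch t-test p-value from the closed-form formulas."""
    from scipy.stats import t as tdist

    na, nb = len(a), len(b)
    ma = sum(a) / na
    mb = sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    se2 = va / na + vb / nb
    t = (ma - mb) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return 2.0 * tdist.sf(abs(t), df)


def auc_pair_count(scores, labels):
    """AUC as concordant-pair fraction with half-credit ties."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def binom_tail_geq(n, k, p):
    """P(X >= k) for X ~ Binomial(n, p) by direct summation."""
    return sum(math.comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(k, n + 1))
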