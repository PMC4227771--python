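"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written from first principles (explicit BFS,
pair enumeration, exhaustive subset scans) and shares no code with the
package under test.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np


def bfs_reachable(nodes, edges, start):
    """Nodes reachable from start by directed paths (self-loops ignored,
    start excluded unless on a cycle through others)."""
    adj = {n: set() for n in nodes}
    for u, v in edges:
        if u != v:
            adj[u].add(v)
    seen = set()
    stack = [start]
    first = True
    while stack:
        x = stack.pop()
        for y in adj[x]:
            if y not in seen:
                seen.add(y)
                stack.append(y)
        first = False
    return seen


def scc_partition(nodes, edges):
    """SCCs by pairwise mutual reachability."""
    reach = {n: bfs_reachable(nodes, edges, n) | {n} for n in nodes}
    comps = []
    assigned = set()
    for n in sorted(nodes):
        if n in assigned:
            continue
        comp = {m for m in nodes if m in reach[n] and n in reach[m]}
        comps.append(frozenset(comp))
        assigned |= comp
    return comps


def vertex_sort_oracle(nodes, edges):
    """Layers and level spans via reachability-derived condensation plus the
    degree rules, independent of the implementation's algorithms.

    Returns (layer, span, height) with layer/node -> str and span/node ->
    (low, high).
    """
    comps = sorted(scc_partition(nodes, edges), key=min)
    cid = {n: i for i, c in enumerate(comps) for n in c}
    dag_edges = {
        (cid[u], cid[v]) for u, v in edges if u != v and cid[u] != cid[v]
    }
    nodes_d = set(range(len(comps)))
    succ = {i: {b for a, b in dag_edges if a == i} for i in nodes_d}
    pred = {i: {a for a, b in dag_edges if b == i} for i in nodes_d}

    def longest_to_sink(i, memo):
        if i in memo:
            return memo[i]
        memo[i] = 0
        if succ[i]:
            memo[i] = 1 + max(longest_to_sink(j, memo) for j in succ[i])
        return memo[i]

    def longest_from_source(i, memo):
        if i in memo:
            return memo[i]
        memo[i] = 0
        if pred[i]:
            memo[i] = 1 + max(longest_from_source(j, memo) for j in pred[i])
        return memo[i]

    m1, m2 = {}, {}
    low = {i: 1 + longest_to_sink(i, m1) for i in nodes_d}
    height = max(low.values())
    high = {i: height - longest_from_source(i, m2) for i in nodes_d}

    layer = {}
    span = {}
    for n in nodes:
        i = cid[n]
        span[n] = (low[i], high[i])
        if len(comps[i]) >= 2:
            layer[n] = "core"
        else:
            ind, outd = len(pred[i]), len(succ[i])
            if ind == 0 and outd == 0:
                layer[n] = "isolated"
            elif ind == 0:
                layer[n] = "top"
            elif outd == 0:
                layer[n] = "bottom"
            else:
                layer[n] = "core"
    return layer, span, height


def lrc_oracle(nodes, edges, v):
    return len(bfs_reachable(nodes, edges, v) - {v}) / (len(nodes) - 1)


def grc_oracle(nodes, edges):
    lrc = {n: lrc_oracle(nodes, edges, n) for n in nodes}
    cmax = max(lrc.values())
    return sum(cmax - lrc[n] for n in sorted(nodes)) / (len(nodes) - 1)


def rand_index_oracle(labels1, labels2):
    """Pair enumeration over a common item list."""
    items = sorted(labels1)
    agree = 0
    total = 0
    for a, b in combinations(items, 2):
        total += 1
        same1 = labels1[a] == labels1[b]
        same2 = labels2[a] == labels2[b]
        if same1 == same2:
            agree += 1
    return agree / total


def hypergeom_oracle(N, K, n, x, direction):
    """Tail probability by exhaustive enumeration of all C(N, n) samples."""
    universe = list(range(N))
    klass = set(range(K))
    hits = 0
    total = 0
    for sample in combinations(universe, n):
        total += 1
        overlap = len(klass & set(sample))
        if direction == "enrichment" and overlap >= x:
            hits += 1
        if direction == "depletion" and overlap <= x:
            hits += 1
    return hits / total


def wilcoxon_exact_oracle(a, b, alternative):
    """Exact Mann-Whitney p by enumerating every split of the pooled sample."""
    a = list(a)
    b = list(b)
    pooled = a + b
    n, m = len(a), len(b)

    def u_stat(xs, ys):
        u = 0.0
        for x in xs:
            for y in ys:
                if x > y:
                    u += 1.0
                elif x == y:
                    u += 0.5
        return u

    u_obs = u_stat(a, b)
    idx = range(n + m)
    total = 0
    le = 0
    ge = 0
    for pick in combinations(idx, n):
        xs = [pooled[i] for i in pick]
        ys = [pooled[i] for i in idx if i not in pick]
        u = u_stat(xs, ys)
        total += 1
        if u <= u_obs + 1e-12:
            le += 1
        if u >= u_obs - 1e-12:
            ge += 1
    if alternative == "less":
        return le / total
    if alternative == "greater":
        return ge / total
    return min(1.0, 2.0 * min(le, ge) / total)


def biclique_oracle(edges, members, min_regulators=2):
    """All maximal (R, B) bicliques of the regulator -> target relation by
    subset brute force with explicit maximality filtering."""
    targets = {}
    for u, v in edges:
        targets.setdefault(u, set()).add(v)
    present = sorted(m for m in members if targets.get(m))
    cands = []
    for r in range(min_regulators, len(present) + 1):
        for R in combinations(present, r):
            B = set.intersection(*(targets[m] for m in R))
            if B:
                cands.append((frozenset(R), frozenset(B)))
    out = set()
    for R, B in cands:
        closure_R = frozenset(m for m in present if targets[m] >= B)
        if closure_R == R:
            out.add((R, B))
    return out


def ward_merge_oracle(points):
    """Exhaustive Ward agglomeration: at each step evaluate every cluster
    pair's variance-increase cost and merge the minimum (ties broken by the
    smallest pair of cluster indices).  Returns the merge order as a list of
    frozenset pairs of original point indices."""
    points = np.asarray(points, dtype=float)
    clusters = [[i] for i in range(len(points))]
    merges = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                a = points[clusters[i]]
                b = points[clusters[j]]
                na, nb = len(a), len(b)
                d = a.mean(axis=0) - b.mean(axis=0)
                cost = na * nb / (na + nb) * float(d @ d)
                if best is None or cost < best[0] - 1e-12:
                    best = (cost, i, j)
        _, i, j = best
        merges.append((frozenset(clusters[i]), frozenset(clusters[j])))
        clusters = (
            [clusters[k] for k in range(len(clusters)) if k not in (i, j)]
            + [clusters[i] + clusters[j]]
        )
    return merges


def scipy_linkage_merges(Z, n):
    """Translate a scipy linkage matrix into the same merge-order
    representation as :func:`ward_merge_oracle`."""
    members = {i: frozenset([i]) for i in range(n)}
    merges = []
    for k, (a, b, _h, _c) in enumerate(Z):
        sa, sb = members[int(a)], members[int(b)]
        merges.append((sa, sb))
        members[n + k] = sa | sb
    return merges


def pca_scores_oracle(X, n_components):
    """PCA scores via eigendecomposition of the covariance matrix."""
    X = np.asarray(X, dtype=float)
    Xc = X - X.mean(axis=0)
    C = Xc.T @ Xc / (len(X) - 1)
    w, V = np.linalg.eigh(C)
    order = np.argsort(w)[::-1][:n_components]
    return Xc @ V[:, order]


def random_digraph(rng, n_max=10, p=0.25):
    n = int(rng.integers(2, n_max + 1))
    nodes = [f"n{i}" for i in range(n)]
    edges = {
        (nodes[i], nodes[j])
        for i in range(n)
        for j in range(n)
        if rng.random() < p
    }
    if not edges:
        edges = {(nodes[0], nodes[1])}
    return nodes, edges
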