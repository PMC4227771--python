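"""Three-layer hierarchy decomposition and reaching centrality.

A directed regulatory network is summarised into top / core / bottom layers by
vertex sorting: strongly connected components (SCCs) are collapsed into
supernodes forming a condensation DAG; leaf removal on the DAG and on its
transpose assigns each supernode a level span; degree rules on the condensation
assign layers.  Every member of a non-trivial SCC is core.  A singleton
supernode is top if it only regulates (condensation in-degree 0, out-degree
>= 1), bottom if it is only regulated, core if both, and isolated if neither.

Self-loops are removed before SCC / leaf-removal / reachability computation: a
single autoregulating TF is not a hierarchy of its own.  They are retained by
the degree-based hub statistics elsewhere.

Local reaching centrality (LRC) of a node is the fraction of the other N-1
nodes it reaches by directed paths; the global reaching centrality (GRC)
averages the gap to the maximum LRC and measures how top-heavy the network is.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import networkx as nx

from .network_io import DirectedNetwork

LAYER_TOP = "top"
LAYER_CORE = "core"
LAYER_BOTTOM = "bottom"
LAYER_ISOLATED = "isolated"
LAYERS = (LAYER_TOP, LAYER_CORE, LAYER_BOTTOM, LAYER_ISOLATED)

#: ordered categories of non-self links between layers
LINK_CATEGORIES = (
    "within_top",
    "top_core",
    "top_bottom",
    "within_core",
    "core_top",
    "core_bottom",
    "within_bottom",
    "bottom_any",
    "involving_isolated",
)


@dataclass(frozen=True)
class HierarchyDecomposition:
    """Per-node layer assignment, SCC membership and leaf-removal level spans.

    Levels count from 1 at the bottom of the condensation DAG up to the
    total number of leaf-removal rounds ``height``.
    """

    scc_id: Mapping[str, int]
    layer: Mapping[str, str]
    level_span: Mapping[str, tuple[int, int]]
    height: int

    def nodes_in_layer(self, layer: str) -> frozenset[str]:
        return frozenset(n for n, l in self.layer.items() if l == layer)


@dataclass(frozen=True)
class LinkDistribution:
    """Counts and fractions of non-self edges per layer-pair category."""

    counts: Mapping[str, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def fractions(self) -> dict[str, float]:
        t = self.total
        if t == 0:
            return {c: 0.0 for c in LINK_CATEGORIES}
        return {c: self.counts[c] / t for c in LINK_CATEGORIES}


def strongly_connected_components(net: DirectedNetwork) -> dict[str, int]:
    """Map each node to an SCC id; ids are assigned in order of the smallest
    member symbol, so the mapping is deterministic."""
    if not net.nodes:
        raise ValueError("empty network")
    g = net.to_networkx(drop_self_loops=True)
    comps = sorted(nx.strongly_connected_components(g), key=min)
    return {node: i for i, comp in enumerate(comps) for node in comp}


def _condensation(net: DirectedNetwork) -> tuple[dict[str, int], nx.DiGraph]:
    scc = strongly_connected_components(net)
    dag = nx.DiGraph()
    dag.add_nodes_from(set(scc.values()))
    for u, v in net.edges:
        if u != v and scc[u] != scc[v]:
            dag.add_edge(scc[u], scc[v])
    return scc, dag


def _leaf_removal_rounds(dag: nx.DiGraph) -> dict[int, int]:
    """Round (1-based) at which each supernode is deleted when out-degree-0
    supernodes are removed repeatedly."""
    out_deg = {n: dag.out_degree(n) for n in dag.nodes}
    preds = {n: list(dag.predecessors(n)) for n in dag.nodes}
    frontier = [n for n, d in out_deg.items() if d == 0]
    rounds: dict[int, int] = {}
    r = 0
    while frontier:
        r += 1
        nxt: list[int] = []
        for n in frontier:
            rounds[n] = r
        for n in frontier:
            for p in preds[n]:
                out_deg[p] -= 1
                if out_deg[p] == 0 and p not in rounds:
                    nxt.append(p)
        frontier = nxt
    return rounds


def vertex_sort(net: DirectedNetwork) -> HierarchyDecomposition:
    """Vertex-sort decomposition of a directed network.

    Collapses SCCs to supernodes, runs leaf removal on the condensation DAG
    and on its transpose to obtain level spans, and assigns top / core /
    bottom / isolated layers by the degree rules described in the module
    docstring.
    """
    scc, dag = _condensation(net)
    low_rounds = _leaf_removal_rounds(dag)
    high_rounds = _leaf_removal_rounds(dag.reverse(copy=True))
    height = max(low_rounds.values())

    scc_sizes: dict[int, int] = {}
    for sid in scc.values():
        scc_sizes[sid] = scc_sizes.get(sid, 0) + 1

    layer: dict[str, str] = {}
    span: dict[str, tuple[int, int]] = {}
    for node, sid in scc.items():
        low = low_rounds[sid]
        high = height - high_rounds[sid] + 1
        span[node] = (low, high)
        if scc_sizes[sid] >= 2:
            layer[node] = LAYER_CORE
            continue
        ind, outd = dag.in_degree(sid), dag.out_degree(sid)
        if ind == 0 and outd == 0:
            layer[node] = LAYER_ISOLATED
        elif ind == 0:
            layer[node] = LAYER_TOP
        elif outd == 0:
            layer[node] = LAYER_BOTTOM
        else:
            layer[node] = LAYER_CORE
    return HierarchyDecomposition(scc_id=scc, layer=layer, level_span=span, height=height)


def layer_proportions(decomp: HierarchyDecomposition) -> dict[str, float]:
    """Fractions of non-isolated nodes per layer (summing to 1) plus the
    isolated fraction over all nodes, under key ``isolated``."""
    n_total = len(decomp.layer)
    counts = {l: 0 for l in LAYERS}
    for l in decomp.layer.values():
        counts[l] += 1
    n_hier = n_total - counts[LAYER_ISOLATED]
    out = {
        l: (counts[l] / n_hier if n_hier else 0.0)
        for l in (LAYER_TOP, LAYER_CORE, LAYER_BOTTOM)
    }
    out[LAYER_ISOLATED] = counts[LAYER_ISOLATED] / n_total if n_total else 0.0
    return out


def link_distribution(net: DirectedNetwork, decomp: HierarchyDecomposition) -> LinkDistribution:
    """Classify every non-self edge into exactly one layer-pair category."""
    if set(decomp.layer) != set(net.nodes):
        raise ValueError("decomposition node set does not match the network")
    counts = {c: 0 for c in LINK_CATEGORIES}
    for u, v in net.edges:
        if u == v:
            continue
        lu, lv = decomp.layer[u], decomp.layer[v]
        if LAYER_ISOLATED in (lu, lv):
            cat = "involving_isolated"
        elif lu == LAYER_BOTTOM:
            cat = "bottom_any"
        elif lu == LAYER_TOP:
            cat = {LAYER_TOP: "within_top", LAYER_CORE: "top_core", LAYER_BOTTOM: "top_bottom"}[lv]
        else:  # core source
            cat = {LAYER_TOP: "core_top", LAYER_CORE: "within_core", LAYER_BOTTOM: "core_bottom"}[lv]
        counts[cat] += 1
    return LinkDistribution(counts=counts)


def local_reaching_centrality(net: DirectedNetwork, v: str) -> float:
    """Fraction of the other N-1 nodes reachable from ``v`` by directed paths
    (self-loops ignored)."""
    if v not in net.nodes:
        raise KeyError(f"unknown node {v!r}")
    if net.n_nodes < 2:
        raise ValueError("LRC requires a network with >= 2 nodes")
    g = net.to_networkx(drop_self_loops=True)
    return len(nx.descendants(g, v)) / (net.n_nodes - 1)


def all_reaching_centralities(net: DirectedNetwork) -> dict[str, float]:
    """LRC for every node.

    Computed on the condensation so that members of one SCC share one
    reachability query.
    """
    if net.n_nodes < 2:
        raise ValueError("LRC requires a network with >= 2 nodes")
    scc, dag = _condensation(net)
    sizes: dict[int, int] = {}
    for sid in scc.values():
        sizes[sid] = sizes.get(sid, 0) + 1
    reach: dict[int, int] = {}
    for sid in nx.topological_sort(dag.reverse(copy=False)):
        nodes_reached = sizes[sid]  # own SCC members (excluding self later)
        seen: set[int] = set()
        stack = list(dag.successors(sid))
        while stack:
            t = stack.pop()
            if t in seen:
                continue
            seen.add(t)
            stack.extend(dag.successors(t))
        nodes_reached += sum(sizes[t] for t in seen)
        reach[sid] = nodes_reached
    denom = net.n_nodes - 1
    return {node: (reach[scc[node]] - 1) / denom for node in net.nodes}


def global_reaching_centrality(net: DirectedNetwork) -> float:
    """GRC = sum_v (C_max - LRC(v)) / (N - 1)."""
    lrc = all_reaching_centralities(net)
    c_max = max(lrc.values())
    # summation in sorted node order keeps the result bit-reproducible
    return sum(c_max - lrc[n] for n in sorted(lrc)) / (net.n_nodes - 1)


def lrc_layer_ordering_check(
    net: DirectedNetwork, decomp: HierarchyDecomposition
) -> list[tuple[str, str, float, float]]:
    """All (upper-layer node, lower-layer node) pairs violating the strict
    LRC ordering top > core > bottom.

    Returns tuples ``(upper, lower, lrc_upper, lrc_lower)`` for every pair of
    a top node with a core node, and of a core node with a bottom node, where
    the upper node's LRC is not strictly greater.
    """
    lrc = all_reaching_centralities(net)
    violations: list[tuple[str, str, float, float]] = []
    pairs = (
        (decomp.nodes_in_layer(LAYER_TOP), decomp.nodes_in_layer(LAYER_CORE)),
        (decomp.nodes_in_layer(LAYER_CORE), decomp.nodes_in_layer(LAYER_BOTTOM)),
    )
    for upper, lower in pairs:
        for u in sorted(upper):
            for l in sorted(lower):
                if lrc[u] <= lrc[l]:
                    violations.append((u, l, lrc[u], lrc[l]))
    return violations
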