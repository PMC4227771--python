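"""Hub identification, hypergeometric layer enrichment, tissue-expression
entropy and Wilcoxon rank-sum comparisons.

Hubs are the top 20% of TFs by out-degree (or total degree for induced
specific subnetworks); nodes tied with the rank-cutoff degree are included.
Layer enrichment uses one-tailed hypergeometric tests with the network's own
TF set as the universe.  Expression stability is measured by the relative
entropy of a gene's tissue profile: log2(T) + sum_j f_j log2(f_j) with
f_j the expression fraction in tissue j; 0 for perfectly uniform expression,
log2(T) for single-tissue expression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .hierarchy import HierarchyDecomposition, LAYER_BOTTOM, LAYER_CORE, LAYER_TOP
from .network_io import DirectedNetwork, ExpressionMatrix, GeneSet, NetworkCollection


@dataclass(frozen=True)
class EnrichmentResult:
    """One hypergeometric tail test: overlap x between a class of size K and
    a sample of size n drawn from a universe of size N."""

    N: int
    K: int
    n: int
    x: int
    direction: str
    p_value: float

    def __post_init__(self) -> None:
        if not 0 <= self.x <= min(self.K, self.n) <= self.N:
            raise ValueError("inconsistent hypergeometric counts")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def hubs(
    net: DirectedNetwork, fraction: float = 0.2, degree_mode: str = "out"
) -> GeneSet:
    """The top ``fraction`` of TFs by degree, ties at the cutoff included.

    ``degree_mode``: ``out`` ranks by out-degree (a self-loop counts once),
    ``total`` by in+out degree (a self-loop counts twice).
    """
    if net.n_nodes == 0:
        raise ValueError("empty network")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if degree_mode == "out":
        deg = net.out_degrees()
    elif degree_mode == "total":
        deg = net.total_degrees()
    else:
        raise ValueError(f"degree_mode must be 'out' or 'total', got {degree_mode!r}")
    ranked = sorted(net.nodes, key=lambda n: (-deg[n], n))
    cutoff_rank = math.ceil(fraction * net.n_nodes)
    threshold = deg[ranked[cutoff_rank - 1]]
    members = frozenset(n for n in net.nodes if deg[n] >= threshold)
    return GeneSet(name=f"{net.name}_hubs_{degree_mode}", members=members)


def hypergeom_test(
    universe: GeneSet | frozenset[str],
    class_set: GeneSet | frozenset[str],
    sample: GeneSet | frozenset[str],
    direction: str = "enrichment",
) -> EnrichmentResult:
    """One-tailed hypergeometric test of the overlap between ``class_set``
    and ``sample`` within ``universe``.

    enrichment: p = P[X >= x]; depletion: p = P[X <= x], where X is
    hypergeometric(N, K, n).  The class is intersected with the universe
    before testing; the sample must be a subset of the universe.
    """
    U = universe.members if isinstance(universe, GeneSet) else frozenset(universe)
    C = class_set.members if isinstance(class_set, GeneSet) else frozenset(class_set)
    S = sample.members if isinstance(sample, GeneSet) else frozenset(sample)
    if not S <= U:
        raise ValueError("sample is not a subset of the universe")
    C = C & U
    N, K, n, x = len(U), len(C), len(S), len(C & S)
    dist = stats.hypergeom(N, K, n)
    if direction == "enrichment":
        p = float(dist.sf(x - 1))
    elif direction == "depletion":
        p = float(dist.cdf(x))
    else:
        raise ValueError(f"direction must be 'enrichment' or 'depletion', got {direction!r}")
    return EnrichmentResult(N=N, K=K, n=n, x=x, direction=direction, p_value=min(p, 1.0))


def layer_enrichment_table(
    collection: NetworkCollection,
    decompositions: dict[str, HierarchyDecomposition],
    gene_sets: list[GeneSet],
    hub_mode: str = "out",
    hub_fraction: float = 0.2,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Enrichment/depletion of hubs and of each gene set in every layer of
    every network.

    One row per network x layer x TF class, with both tail p-values and a
    +/- call at level ``alpha`` on the smaller tail (blank when neither tail
    is significant).  The universe is the network's own TF set.
    """
    rows = []
    for net in collection:
        decomp = decompositions[net.name]
        classes = [hubs(net, fraction=hub_fraction, degree_mode=hub_mode)] + gene_sets
        class_names = ["hubs"] + [gs.name for gs in gene_sets]
        universe = frozenset(net.nodes)
        for layer in (LAYER_TOP, LAYER_CORE, LAYER_BOTTOM):
            sample = decomp.nodes_in_layer(layer)
            for cname, cset in zip(class_names, classes):
                enr = hypergeom_test(universe, cset, sample, "enrichment")
                dep = hypergeom_test(universe, cset, sample, "depletion")
                if enr.p_value <= alpha and enr.p_value <= dep.p_value:
                    call = "+"
                elif dep.p_value <= alpha and dep.p_value < enr.p_value:
                    call = "-"
                else:
                    call = ""
                rows.append(
                    (net.name, layer, cname, enr.N, enr.K, enr.n, enr.x,
                     enr.p_value, dep.p_value, call)
                )
    return pd.DataFrame(
        rows,
        columns=["network", "layer", "class", "N", "K", "n", "x",
                 "p_enrich", "p_deplete", "call"],
    )


def expression_entropy(e) -> float:
    """Relative entropy of a tissue-expression row.

    log2(T) + sum_j f_j log2(f_j) with f_j = e_j / sum_k e_k and the
    convention 0 * log2(0) = 0.  Zero iff expression is identical in all T
    tissues; log2(T) iff concentrated in one tissue.
    """
    e = np.asarray(e, dtype=float)
    if e.ndim != 1 or e.size == 0:
        raise ValueError("expected a non-empty 1-D expression row")
    if (e < 0).any():
        raise ValueError("negative expression value")
    total = e.sum()
    if total == 0:
        raise ValueError("all-zero expression row has no tissue distribution")
    f = e / total
    nz = f > 0
    # algebraically log2(T) + sum f log2 f, folded into one logarithm so a
    # perfectly uniform row yields exactly 0 (each e_j * T / total == 1)
    return float(np.sum(f[nz] * np.log2(e[nz] * e.size / total)))


def entropy_table(expr: ExpressionMatrix) -> pd.DataFrame:
    """Per-gene relative entropies (degenerate all-zero rows excluded)."""
    rows = [
        (g, expression_entropy(expr.row(g)))
        for g in expr.genes
        if g not in expr.degenerate_genes
    ]
    return pd.DataFrame(rows, columns=["gene", "entropy"])


def wilcoxon_rank_sum(a, b, alternative: str = "two-sided") -> float:
    """Wilcoxon rank-sum (Mann-Whitney) p-value.

    ``alternative='less'`` tests whether ``a`` tends to be smaller than
    ``b``.  Uses exact null enumeration when n+m <= 12 and there are no
    ties, otherwise the normal approximation with tie and continuity
    corrections.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    no_ties = len(np.unique(pooled)) == pooled.size
    method = "exact" if (a.size + b.size <= 12 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative=alternative, method=method, use_continuity=True
    )
    return float(res.pvalue)


def entropy_comparison(
    expr: ExpressionMatrix, hk_tfs: GeneSet
) -> tuple[pd.DataFrame, float]:
    """Compare expression-entropy distributions of HK-involved TF genes vs
    the remaining genes.

    Returns the per-gene entropy table (columns gene, entropy, group with
    group in {hk, other}) and the one-sided Wilcoxon p-value for the
    alternative that the HK group has smaller entropy (i.e. is stabler).
    """
    table = entropy_table(expr)
    if table.empty:
        raise ValueError("no non-degenerate genes in the expression matrix")
    in_hk = table["gene"].isin(hk_tfs.members)
    if not in_hk.any():
        raise ValueError(f"gene set {hk_tfs.name!r} does not intersect expression genes")
    table = table.assign(group=np.where(in_hk, "hk", "other"))
    others = table.loc[table["group"] == "other", "entropy"]
    if others.empty:
        raise ValueError("no genes outside the HK group to compare against")
    p = wilcoxon_rank_sum(
        table.loc[table["group"] == "hk", "entropy"], others, alternative="less"
    )
    return table, p


def empirical_rank_pvalue(values, query_index: int, alternative: str = "less") -> float:
    """One-sided empirical rank p-value of one observation within a set.

    ``less``: probability under exchangeability of a value as small as the
    query's, p = rank / n with midranks on ties; ``greater`` analogous.
    Used e.g. to ask whether one network's top-layer fraction is an outlier
    within the collection.
    """
    values = np.asarray(values, dtype=float)
    q = values[query_index]
    n = values.size
    if alternative == "less":
        r = np.sum(values < q) + 0.5 * (np.sum(values == q) - 1) + 1
    elif alternative == "greater":
        r = np.sum(values > q) + 0.5 * (np.sum(values == q) - 1) + 1
    else:
        raise ValueError("alternative must be 'less' or 'greater'")
    return float(r / n)
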