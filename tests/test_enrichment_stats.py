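from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tfhier.enrichment_stats import (
    empirical_rank_pvalue,
    entropy_comparison,
    expression_entropy,
    hubs,
    hypergeom_test,
    layer_enrichment_table,
    wilcoxon_rank_sum,
)
from tfhier.hierarchy import vertex_sort
from tfhier.network_io import DirectedNetwork, ExpressionMatrix, GeneSet, NetworkCollection

from tests.conftest import net
from tests.oracles import hypergeom_oracle, wilcoxon_exact_oracle


# --- hubs -------------------------------------------------------------------

def test_hubs_distinct_out_degrees():
    edges = []
    names = [f"v{i}" for i in range(10)]
    for i, n in enumerate(names):  # node v_i has out-degree i
        edges += [(n, names[(i + j + 1) % 10]) for j in range(i)]
    network = DirectedNetwork.from_edges("g", edges, extra_nodes=names)
    assert hubs(network, fraction=0.2).members == {"v8", "v9"}


def test_hubs_fraction_one_returns_all():
    n = net("g", ("a", "b"), ("b", "c"))
    assert hubs(n, fraction=1.0).members == n.nodes


def test_hubs_tie_inclusion():
    # out-degrees (5,5,5,1,1): the rank-1 cutoff degree is 5, all three
    # degree-5 nodes are hubs
    edges = []
    sinks = [f"s{i}" for i in range(5)]
    for h in ("h1", "h2", "h3"):
        edges += [(h, s) for s in sinks]
    edges += [("l1", "s0"), ("l2", "s1")]
    network = DirectedNetwork.from_edges("g", edges, extra_nodes=["h1", "h2", "h3", "l1", "l2"])
    got = hubs(
        DirectedNetwork.from_edges(
            "g", [(u, v) for u, v in edges], extra_nodes=["h1", "h2", "h3", "l1", "l2"]
        ),
        fraction=0.2,
    )
    # universe includes the 5 sinks, N=10, cutoff rank 2 -> degree 5
    assert {"h1", "h2", "h3"} <= got.members
    assert not {"l1", "l2"} & got.members


def test_hubs_monotone_in_fraction():
    rng = np.random.default_rng(21)
    names = [f"v{i}" for i in range(12)]
    edges = {(a, b) for a in names for b in names if a != b and rng.random() < 0.3}
    n = DirectedNetwork.from_edges("g", edges, extra_nodes=names)
    prev: frozenset[str] = frozenset()
    for f in (0.1, 0.2, 0.5, 0.8, 1.0):
        cur = hubs(n, fraction=f).members
        assert prev <= cur
        prev = cur


def test_hubs_total_degree_counts_self_loops_twice():
    n = net("g", ("a", "a"), ("b", "c"), ("c", "b"), ("b", "d"))
    deg = n.total_degrees()
    assert deg["a"] == 2 and deg["b"] == 3


# --- hypergeometric ---------------------------------------------------------

def test_hypergeom_small_examples():
    U = frozenset(range(5))
    C = frozenset(range(2))
    res = hypergeom_test(U, C, frozenset({0, 1}), "enrichment")
    assert res.p_value == pytest.approx(0.1)  # 1 / C(5,2)
    res = hypergeom_test(U, C, frozenset({2, 3}), "depletion")
    assert res.p_value == pytest.approx(0.3)  # C(3,2) / C(5,2)
    res = hypergeom_test(U, U, frozenset({0, 1}), "enrichment")
    assert res.p_value == 1.0


def test_hypergeom_matches_enumeration_oracle():
    rng = np.random.default_rng(33)
    for _ in range(60):
        N = int(rng.integers(2, 13))
        K = int(rng.integers(0, N + 1))
        n = int(rng.integers(1, N + 1))
        universe = frozenset(range(N))
        klass = frozenset(range(K))
        sample = frozenset(int(i) for i in rng.choice(N, size=n, replace=False))
        x = len(klass & sample)
        for direction in ("enrichment", "depletion"):
            got = hypergeom_test(universe, klass, sample, direction).p_value
            assert got == pytest.approx(hypergeom_oracle(N, K, n, x, direction))


def test_hypergeom_tail_identity():
    rng = np.random.default_rng(61)
    from scipy import stats

    for _ in range(30):
        N = int(rng.integers(2, 40))
        K = int(rng.integers(0, N + 1))
        n = int(rng.integers(1, N + 1))
        universe = frozenset(range(N))
        klass = frozenset(range(K))
        sample = frozenset(int(i) for i in rng.choice(N, size=n, replace=False))
        x = len(klass & sample)
        pe = hypergeom_test(universe, klass, sample, "enrichment").p_value
        pd_ = hypergeom_test(universe, klass, sample, "depletion").p_value
        assert pe + pd_ == pytest.approx(1 + stats.hypergeom(N, K, n).pmf(x))


def test_hypergeom_sample_outside_universe():
    with pytest.raises(ValueError):
        hypergeom_test(frozenset({1}), frozenset({1}), frozenset({2}), "enrichment")


# --- layer enrichment table -------------------------------------------------

def test_layer_enrichment_planted_core_class():
    # core cycle of 12 holds the entire class; top/bottom are class-free
    core = [f"c{i}" for i in range(12)]
    edges = [(core[i], core[(i + 1) % 12]) for i in range(12)]
    edges += [(f"t{j}", core[j]) for j in range(4)]
    edges += [(core[4 + j], f"b{j}") for j in range(4)]
    network = DirectedNetwork.from_edges("g", edges)
    coll = NetworkCollection(networks=(network,), class_label={"g": "x"})
    decomp = {"g": vertex_sort(network)}
    klass = GeneSet("planted", frozenset(core))
    table = layer_enrichment_table(coll, decomp, [klass])
    sub = table[table["class"] == "planted"].set_index("layer")
    assert sub.loc["core", "call"] == "+"
    assert sub.loc["top", "call"] == "-"
    assert sub.loc["bottom", "call"] == "-"
    # row count = networks x 3 layers x (hubs + gene sets)
    assert len(table) == 1 * 3 * 2


def test_layer_enrichment_disjoint_class_zero_overlap(tiny_collection):
    decomps = {n.name: vertex_sort(n) for n in tiny_collection}
    table = layer_enrichment_table(
        tiny_collection, decomps, [GeneSet("none", frozenset({"ZZ"}))]
    )
    assert (table.loc[table["class"] == "none", "x"] == 0).all()


# --- entropy ----------------------------------------------------------------

def test_entropy_constant_row_is_zero():
    assert expression_entropy(np.full(79, 3.7)) == pytest.approx(0.0, abs=1e-12)


def test_entropy_one_hot_is_log2T():
    for T in (4, 79):
        e = np.zeros(T)
        e[2] = 5.0
        assert expression_entropy(e) == pytest.approx(np.log2(T))


def test_entropy_half_concentrated():
    assert expression_entropy([1.0, 1.0, 0.0, 0.0]) == pytest.approx(1.0)


@given(st.lists(st.floats(min_value=0.01, max_value=100.0), min_size=2, max_size=30))
def test_entropy_bounds_and_scale_invariance(values):
    e = np.array(values)
    h = expression_entropy(e)
    assert -1e-9 <= h <= np.log2(e.size) + 1e-9
    assert expression_entropy(7.3 * e) == pytest.approx(h, abs=1e-9)


def test_entropy_rejects_bad_rows():
    with pytest.raises(ValueError):
        expression_entropy([0.0, 0.0])
    with pytest.raises(ValueError):
        expression_entropy([1.0, -0.5])


# --- Wilcoxon ---------------------------------------------------------------

def test_wilcoxon_separated_samples_exact():
    assert wilcoxon_rank_sum((1, 2, 3), (10, 11, 12), "less") == pytest.approx(0.05)


def test_wilcoxon_identical_samples_two_sided():
    p = wilcoxon_rank_sum((1.0, 2.0, 3.0, 4.0, 5.0), (1.0, 2.0, 3.0, 4.0, 5.0))
    assert p >= 0.99


def test_wilcoxon_exact_matches_split_enumeration():
    rng = np.random.default_rng(55)
    for _ in range(30):
        n = int(rng.integers(2, 6))
        m = int(rng.integers(2, 11 - n))
        pooled = rng.permutation(np.arange(1.0, n + m + 1.0))  # distinct -> exact
        a, b = pooled[:n], pooled[n:]
        for alt in ("less", "greater", "two-sided"):
            assert wilcoxon_rank_sum(a, b, alt) == pytest.approx(
                wilcoxon_exact_oracle(a, b, alt)
            )


def test_wilcoxon_empty_sample():
    with pytest.raises(ValueError):
        wilcoxon_rank_sum([], [1.0])


# --- entropy comparison -----------------------------------------------------

def _matrix(rows: dict[str, np.ndarray]) -> ExpressionMatrix:
    return ExpressionMatrix(
        data=pd.DataFrame(
            {f"t{j}": {g: rows[g][j] for g in rows} for j in range(len(next(iter(rows.values()))))}
        )
    )


def test_entropy_comparison_separates_planted_groups():
    T = 20
    rows = {}
    for i in range(12):  # stable: constant rows
        rows[f"S{i}"] = np.full(T, 10.0 + i)
    rng = np.random.default_rng(9)
    for i in range(12):  # variable: one-tissue concentrated
        e = np.zeros(T)
        e[rng.integers(T)] = 50.0
        rows[f"V{i}"] = e
    expr = _matrix(rows)
    table, p = entropy_comparison(expr, GeneSet("hk", frozenset(f"S{i}" for i in range(12))))
    assert p < 0.01
    assert (table["entropy"] >= 0).all()
    assert set(table["group"]) == {"hk", "other"}


def test_entropy_comparison_all_constant():
    rows = {f"G{i}": np.full(10, 5.0) for i in range(8)}
    expr = _matrix(rows)
    table, p = entropy_comparison(expr, GeneSet("hk", frozenset({"G0", "G1"})))
    assert table["entropy"].abs().max() < 1e-9
    assert p >= 0.99


def test_entropy_comparison_requires_overlap():
    expr = _matrix({"G1": np.full(5, 1.0), "G2": np.full(5, 2.0)})
    with pytest.raises(ValueError):
        entropy_comparison(expr, GeneSet("hk", frozenset({"ZZ"})))


def test_empirical_rank_pvalue():
    vals = [0.30, 0.25, 0.28, 0.06, 0.27]
    assert empirical_rank_pvalue(vals, 3, "less") == pytest.approx(1 / 5)
    assert empirical_rank_pvalue(vals, 0, "greater") == pytest.approx(1 / 5)
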