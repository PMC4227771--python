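from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from tfhier.classify import (
    DegenerateFeaturesWarning,
    Partition,
    classify_collection,
    nnd_feature_matrix,
    pca_project,
    rand_index,
    random_tf_set_sweep,
    reference_partition,
    target_feature_matrix,
    ward_cluster,
)
from tfhier.enrichment_stats import wilcoxon_rank_sum
from tfhier.network_io import DirectedNetwork, GeneSet, NetworkCollection
from tfhier.synthetic_data import generate_collection

from tests.conftest import net
from tests.oracles import (
    pca_scores_oracle,
    rand_index_oracle,
    scipy_linkage_merges,
    ward_merge_oracle,
)


def collection_of(*nets, labels=None):
    labels = labels or {n.name: "c" for n in nets}
    return NetworkCollection(networks=tuple(nets), class_label=labels)


# --- feature matrices -------------------------------------------------------

def test_target_features_single_source():
    coll = collection_of(net("c1", ("S", "X"), ("Y", "Z")))
    fm = target_feature_matrix(coll, GeneSet("A", frozenset({"S"})))
    row = fm.data.loc["c1"]
    assert row["X"] == 1
    assert row.drop("X").sum() == 0


def test_target_features_identical_networks_identical_rows():
    a = net("a", ("S", "X"), ("S", "Y"))
    b = DirectedNetwork.from_edges("b", a.edges)
    fm = target_feature_matrix(collection_of(a, b), GeneSet("A", frozenset({"S"})))
    assert (fm.data.loc["a"] == fm.data.loc["b"]).all()


def test_target_features_match_edge_scan_oracle():
    rng = np.random.default_rng(41)
    nets = []
    for i in range(4):
        n = int(rng.integers(3, 8))
        names = [f"v{j}" for j in range(n)]
        edges = {
            (a, b) for a in names for b in names if a != b and rng.random() < 0.3
        }
        nets.append(DirectedNetwork.from_edges(f"n{i}", edges or {(names[0], names[1])}))
    coll = collection_of(*nets)
    A = GeneSet("A", frozenset({"v0", "v1"}))
    fm = target_feature_matrix(coll, A)
    for net_ in coll:
        for t in fm.feature_tfs:
            expected = int(any(u in A.members and v == t for u, v in net_.edges))
            assert fm.data.loc[net_.name, t] == expected


def test_target_features_disjoint_set_errors(tiny_collection):
    with pytest.raises(ValueError, match="disjoint"):
        target_feature_matrix(tiny_collection, GeneSet("A", frozenset({"ZZZ"})))


def test_nnd_single_edge_and_row_sums(tiny_collection):
    coll = collection_of(net("one", ("A", "B")))
    fm = nnd_feature_matrix(coll)
    assert fm.data.loc["one", "A"] == 0.5
    assert fm.data.loc["one", "B"] == 0.5
    fm2 = nnd_feature_matrix(tiny_collection)
    assert np.allclose(fm2.data.sum(axis=1), 1.0)


# --- PCA --------------------------------------------------------------------

def test_pca_collinear_isometry():
    t = np.array([0.0, 1.0, 3.0, 7.0])
    X = np.outer(t, [1.0, 2.0, 2.0])  # points on one line in 3-space
    df = pd.DataFrame(X, index=list("abcd"))
    proj = pca_project(df, n_components=3)
    # one non-degenerate direction; pairwise distances preserved
    assert proj.shape[1] == 3
    d0 = np.abs(proj.iloc[:, 0].to_numpy()[:, None] - proj.iloc[:, 0].to_numpy())
    dx = np.linalg.norm(X[:, None] - X[None, :], axis=-1)
    assert np.allclose(d0, dx)


def test_pca_centering_invariance():
    rng = np.random.default_rng(4)
    X = rng.normal(size=(6, 5))
    shift = rng.normal(size=5)
    p1 = pca_project(pd.DataFrame(X), 3)
    p2 = pca_project(pd.DataFrame(X + shift), 3)
    assert np.allclose(p1.to_numpy(), p2.to_numpy(), atol=1e-9)


def test_pca_matches_covariance_eigendecomposition():
    rng = np.random.default_rng(8)
    X = rng.normal(size=(5, 4))
    proj = pca_project(pd.DataFrame(X), 3).to_numpy()
    ora = pca_scores_oracle(X, 3)
    for j in range(3):  # sign convention per component
        col = proj[:, j]
        assert np.allclose(col, ora[:, j], atol=1e-8) or np.allclose(
            col, -ora[:, j], atol=1e-8
        )


def test_pca_needs_two_rows():
    with pytest.raises(ValueError):
        pca_project(pd.DataFrame([[1.0, 2.0]]), 2)


# --- Ward -------------------------------------------------------------------

def test_ward_separated_clouds():
    rng = np.random.default_rng(12)
    a = rng.normal(0, 0.05, size=(4, 2))
    b = rng.normal(10, 0.05, size=(4, 2))
    df = pd.DataFrame(np.vstack([a, b]), index=[f"p{i}" for i in range(8)])
    part, _ = ward_cluster(df, k=2)
    groups = {}
    for name, c in part.labels.items():
        groups.setdefault(c, set()).add(name)
    assert sorted(groups.values(), key=len) == sorted(
        [{f"p{i}" for i in range(4)}, {f"p{i}" for i in range(4, 8)}], key=len
    )


def test_ward_k_equals_rows_gives_singletons():
    df = pd.DataFrame(np.eye(4), index=list("abcd"))
    part, _ = ward_cluster(df, k=4)
    assert len(set(part.labels.values())) == 4


def test_ward_merge_order_matches_exhaustive_oracle():
    rng = np.random.default_rng(77)
    for _ in range(20):
        n = int(rng.integers(3, 7))
        X = rng.normal(size=(n, 2))
        df = pd.DataFrame(X, index=[f"p{i}" for i in range(n)])
        _, Z = ward_cluster(df, k=1)
        got = [frozenset(p) | frozenset(q) for p, q in scipy_linkage_merges(Z, n)]
        want = [a | b for a, b in ward_merge_oracle(X)]
        assert got == want


def test_ward_heights_nondecreasing():
    rng = np.random.default_rng(15)
    df = pd.DataFrame(rng.normal(size=(10, 3)))
    _, Z = ward_cluster(df, k=1)
    assert (np.diff(Z[:, 2]) >= -1e-12).all()


def test_ward_k_out_of_range():
    df = pd.DataFrame(np.eye(3))
    with pytest.raises(ValueError):
        ward_cluster(df, k=0)
    with pytest.raises(ValueError):
        ward_cluster(df, k=4)


# --- Rand index -------------------------------------------------------------

def test_rand_index_examples():
    p1 = Partition(labels={"1": 1, "2": 1, "3": 2}, k=2)
    p2 = Partition(labels={"1": 1, "2": 2, "3": 3}, k=3)
    assert rand_index(p1, p1) == 1.0
    assert rand_index(p1, p2) == pytest.approx(2 / 3)
    assert rand_index(p1, p2) == rand_index(p2, p1)


def test_rand_index_matches_pair_enumeration():
    rng = np.random.default_rng(44)
    for _ in range(100):
        n = int(rng.integers(2, 9))
        items = [f"i{j}" for j in range(n)]
        l1 = {i: int(rng.integers(1, 4)) for i in items}
        l2 = {i: int(rng.integers(1, 4)) for i in items}
        p1 = Partition.from_labels(l1)
        p2 = Partition.from_labels(l2)
        assert rand_index(p1, p2) == pytest.approx(rand_index_oracle(l1, l2))


def test_rand_index_mismatched_items():
    p1 = Partition(labels={"a": 1, "b": 1}, k=1)
    p2 = Partition(labels={"a": 1, "c": 1}, k=1)
    with pytest.raises(ValueError):
        rand_index(p1, p2)


def test_rand_index_one_iff_equal_partitions():
    rng = np.random.default_rng(50)
    for _ in range(50):
        items = [f"i{j}" for j in range(6)]
        l1 = {i: int(rng.integers(1, 3)) for i in items}
        l2 = {i: int(rng.integers(1, 3)) for i in items}
        p1, p2 = Partition.from_labels(l1), Partition.from_labels(l2)
        same_partition = {
            frozenset(i for i in items if l1[i] == v) for v in set(l1.values())
        } == {frozenset(i for i in items if l2[i] == v) for v in set(l2.values())}
        assert (rand_index(p1, p2) == 1.0) == same_partition


# --- end-to-end classification ---------------------------------------------

@pytest.fixture(scope="module")
def planted():
    coll, truth = generate_collection(
        n_tfs=60, n_networks=8, class_sizes=[2, 2, 2, 2],
        core_extra_edge_prob=0.01, n_specific_per_network=15,
        marker_set_size=5, n_class_targets=5, n_class_edges=25, seed=17,
    )
    return coll, truth


def test_classify_recovers_planted_classes(planted):
    coll, truth = planted
    ref = Partition.from_labels(dict(coll.class_label))
    part, ri = classify_collection(coll, truth.marker_set, reference=ref)
    assert ri == 1.0
    # reference = produced partition is a fixed point
    assert rand_index(part, part) == 1.0


def test_classify_row_order_invariance(planted):
    coll, truth = planted
    ref = Partition.from_labels(dict(coll.class_label))
    reordered = NetworkCollection(
        networks=tuple(reversed(coll.networks)), class_label=dict(coll.class_label)
    )
    _, ri1 = classify_collection(coll, truth.marker_set, reference=ref)
    _, ri2 = classify_collection(reordered, truth.marker_set, reference=ref)
    assert ri1 == ri2


def test_classify_degenerate_features_warn():
    a = net("a", ("S", "X"))
    b = DirectedNetwork.from_edges("b", a.edges)
    coll = collection_of(a, b, labels={"a": "u", "b": "v"})
    ref = Partition.from_labels({"a": "u", "b": "v"})
    with pytest.warns(DegenerateFeaturesWarning):
        part, ri = classify_collection(
            coll, GeneSet("A", frozenset({"S"})), reference=ref, k=1
        )
    # one cluster vs the 2-singleton reference: the single pair disagrees
    assert ri == rand_index_oracle({"a": 1, "b": 1}, {"a": 1, "b": 2})


def test_reference_partition_merges_classes():
    nets = [net(n, ("A", "B")) for n in ("s1", "e1", "b1", "c1", "v1")]
    coll = collection_of(
        *[DirectedNetwork.from_edges(n.name, n.edges) for n in nets],
        labels={"s1": "stroma", "e1": "epithelia", "b1": "blood",
                "c1": "cancer", "v1": "viscera"},
    )
    ref = reference_partition(coll)
    assert ref.labels["s1"] == ref.labels["e1"]
    assert ref.labels["s1"] != ref.labels["b1"]
    assert len({ref.labels["b1"], ref.labels["c1"], ref.labels["v1"]}) == 3


def test_sweep_deterministic_and_signal_above_permuted_baseline(planted):
    coll, truth = planted
    ref = Partition.from_labels(dict(coll.class_label))
    s1 = random_tf_set_sweep(coll, set_size=5, n_draws=8, seed=2, reference=ref)
    s2 = random_tf_set_sweep(coll, set_size=5, n_draws=8, seed=2, reference=ref)
    assert s1.equals(s2)
    # permuted reference labels destroy the planted class signal
    rng = np.random.default_rng(0)
    names = list(ref.labels)
    permuted = Partition.from_labels(
        {n: ref.labels[names[i]] for n, i in zip(names, rng.permutation(len(names)))}
    )
    s_null = random_tf_set_sweep(coll, set_size=5, n_draws=8, seed=2, reference=permuted)
    assert s1["rand_index"].mean() > s_null["rand_index"].mean()
    p = wilcoxon_rank_sum(s_null["rand_index"], s1["rand_index"], alternative="less")
    assert p < 0.05


def test_sweep_set_size_too_large(tiny_collection):
    ref = Partition.from_labels(dict(tiny_collection.class_label))
    with pytest.raises(ValueError):
        random_tf_set_sweep(tiny_collection, set_size=99, n_draws=2, seed=0, reference=ref)
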