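"""Cell-type classification from TF wiring.

Two feature families describe each network (cell type): binary target
indicators for a small TF set A (entry 1 iff the TF is regulated by some
member of A in that network) and normalized node-degree (NND) profiles.
Feature vectors are reduced with PCA, clustered with Ward agglomeration on
Euclidean distances, and the resulting partition is scored against a
reference with the Rand index.

Feature columns span the union of TFs over all networks (0-filled where a TF
is absent) so that vectors from different networks are comparable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import comb
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.decomposition import PCA

from .network_io import DirectedNetwork, GeneSet, NetworkCollection

#: class labels merged into the four reference categories used when scoring
#: cell-type partitions; labels not listed map to their own category.
DEFAULT_CLASS_MERGES: dict[str, str] = {
    "stroma": "stroma+epithelia",
    "epithelia": "stroma+epithelia",
    "blood": "blood",
    "endothelia": "endothelia",
    "cancer": "cancer+esc+fetal",
    "esc": "cancer+esc+fetal",
    "ESC": "cancer+esc+fetal",
    "fetal": "cancer+esc+fetal",
}


class DegenerateFeaturesWarning(UserWarning):
    """All feature rows are identical; clustering output is arbitrary."""


@dataclass(frozen=True)
class FeatureMatrix:
    """Cell-type x TF feature matrix.

    ``source`` records provenance: ``targets:<set name>`` for binary
    target-indicator features or ``nnd`` for degree profiles.
    """

    data: pd.DataFrame
    source: str

    @property
    def networks(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_tfs(self) -> list[str]:
        return list(self.data.columns)


@dataclass(frozen=True)
class Partition:
    """A labeling of collection members into k clusters."""

    labels: Mapping[str, int]
    k: int

    def __post_init__(self) -> None:
        n_distinct = len(set(self.labels.values()))
        if not 1 <= n_distinct <= len(self.labels):
            raise ValueError("invalid number of clusters")

    @property
    def items(self) -> frozenset[str]:
        return frozenset(self.labels)

    @classmethod
    def from_labels(cls, labels: Mapping[str, object]) -> "Partition":
        distinct = sorted({str(v) for v in labels.values()})
        lut = {v: i + 1 for i, v in enumerate(distinct)}
        return cls(labels={k: lut[str(v)] for k, v in labels.items()}, k=len(distinct))


def reference_partition(
    collection: NetworkCollection,
    merges: Mapping[str, str] | None = None,
) -> Partition:
    """Reference partition from class labels; ``merges`` maps class labels to
    merged category names (defaults to the four-category convention above)."""
    merges = DEFAULT_CLASS_MERGES if merges is None else merges
    cats = {
        name: merges.get(collection.class_label[name], collection.class_label[name])
        for name in collection.names
    }
    return Partition.from_labels(cats)


def target_feature_matrix(collection: NetworkCollection, A: GeneSet) -> FeatureMatrix:
    """Binary matrix: entry (c, t) = 1 iff network c has an edge a -> t for
    some a in A."""
    union = collection.union_nodes()
    if not any(A.members & net.nodes for net in collection):
        raise ValueError(f"TF set {A.name!r} is disjoint from every network")
    rows = np.zeros((len(collection), len(union)), dtype=np.int8)
    col = {t: j for j, t in enumerate(union)}
    for i, net in enumerate(collection):
        for u, v in net.edges:
            if u in A.members:
                rows[i, col[v]] = 1
    df = pd.DataFrame(rows, index=collection.names, columns=union)
    return FeatureMatrix(data=df, source=f"targets:{A.name}")


def nnd_feature_matrix(collection: NetworkCollection) -> FeatureMatrix:
    """Normalized node-degree profiles: (in + out degree) / (2 x edge count)
    per network; rows sum to 1 by the handshake identity."""
    union = collection.union_nodes()
    col = {t: j for j, t in enumerate(union)}
    rows = np.zeros((len(collection), len(union)), dtype=float)
    for i, net in enumerate(collection):
        if net.n_edges == 0:
            raise ValueError(f"network {net.name!r} has no edges")
        denom = 2.0 * net.n_edges
        for t, d in net.total_degrees().items():
            rows[i, col[t]] = d / denom
    df = pd.DataFrame(rows, index=collection.names, columns=union)
    return FeatureMatrix(data=df, source="nnd")


def pca_project(matrix: FeatureMatrix | pd.DataFrame, n_components: int = 7) -> pd.DataFrame:
    """Project rows onto the leading principal components.

    Columns are mean-centered (not scaled); the number of components is
    capped at min(n_components, rows - 1, columns); each component's sign is
    fixed so that its largest-magnitude loading is positive.
    """
    df = matrix.data if isinstance(matrix, FeatureMatrix) else matrix
    if len(df) < 2:
        raise ValueError("PCA needs at least 2 rows")
    n = min(n_components, len(df) - 1, df.shape[1])
    X = df.to_numpy(dtype=float)
    if np.allclose(X, X[0]):
        warnings.warn(
            "all feature rows are identical; projection is all-zero",
            DegenerateFeaturesWarning,
            stacklevel=2,
        )
    pca = PCA(n_components=n, svd_solver="full")
    scores = pca.fit_transform(X)
    for j in range(n):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            scores[:, j] *= -1.0
    return pd.DataFrame(
        scores, index=df.index, columns=[f"PC{j + 1}" for j in range(n)]
    )


def ward_cluster(points: pd.DataFrame, k: int) -> tuple[Partition, np.ndarray]:
    """Ward minimum-variance agglomeration on Euclidean distances.

    Returns the k-cluster partition (cluster ids 1..k) and the full scipy
    linkage matrix.  Within scipy's linkage, exactly tied merge costs resolve
    by cluster index order, which is deterministic for a fixed row order.
    """
    n = len(points)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    X = points.to_numpy(dtype=float)
    Z = linkage(X, method="ward")
    flat = fcluster(Z, t=k, criterion="maxclust")
    labels = {name: int(c) for name, c in zip(points.index, flat)}
    return Partition(labels=labels, k=len(set(flat))), Z


def linkage_to_newick(Z: np.ndarray, names: Sequence[str]) -> str:
    """Export a scipy linkage matrix as a Newick string with branch lengths
    equal to merge-height differences."""
    n = len(names)
    heights = {i: 0.0 for i in range(n)}
    subtree = {i: str(names[i]) for i in range(n)}
    for row_idx, (a, b, h, _cnt) in enumerate(Z):
        a, b = int(a), int(b)
        node = n + row_idx
        la = h - heights[a]
        lb = h - heights[b]
        subtree[node] = f"({subtree[a]}:{la:.6g},{subtree[b]}:{lb:.6g})"
        heights[node] = h
    return subtree[n + len(Z) - 1] + ";"


def rand_index(p1: Partition, p2: Partition) -> float:
    """Fraction of item pairs on which two partitions agree (placed together
    in both or apart in both), out of C(n, 2)."""
    if p1.items != p2.items:
        raise ValueError("partitions cover different item sets")
    items = sorted(p1.items)
    n = len(items)
    if n < 2:
        raise ValueError("Rand index needs >= 2 items")
    l1 = [p1.labels[i] for i in items]
    l2 = [p2.labels[i] for i in items]
    ct = pd.crosstab(pd.Series(l1), pd.Series(l2)).to_numpy()
    sum_ij = sum(comb(int(x), 2) for x in ct.ravel())
    sum_a = sum(comb(int(x), 2) for x in ct.sum(axis=1))
    sum_b = sum(comb(int(x), 2) for x in ct.sum(axis=0))
    total = comb(n, 2)
    return (total + 2 * sum_ij - sum_a - sum_b) / total


def classify_collection(
    collection: NetworkCollection,
    A: GeneSet | str,
    reference: Partition,
    n_components: int = 7,
    k: int = 4,
) -> tuple[Partition, float]:
    """Full classification pipeline: feature matrix (target indicators for a
    TF set ``A``, or NND profiles when ``A == "NND"``) -> PCA -> Ward(k) ->
    Rand index against the reference partition."""
    if isinstance(A, str):
        if A.lower() != "nnd":
            raise ValueError(f"unknown feature mode {A!r}; pass a GeneSet or 'NND'")
        features = nnd_feature_matrix(collection)
    else:
        features = target_feature_matrix(collection, A)
    points = pca_project(features, n_components=n_components)
    partition, _ = ward_cluster(points, k=k)
    return partition, rand_index(partition, reference)


def random_tf_set_sweep(
    collection: NetworkCollection,
    set_size: int,
    n_draws: int,
    seed: int,
    reference: Partition,
    n_components: int = 7,
    k: int = 4,
) -> pd.DataFrame:
    """Rand indices obtained from ``n_draws`` uniformly drawn TF sets of the
    given size (drawn without replacement from the union regulator set).

    Returns a table with columns draw, tfs (semicolon-joined), rand_index.
    """
    regulators: set[str] = set()
    for net in collection:
        regulators |= {u for u, _ in net.edges}
    regulators_sorted = sorted(regulators)
    if set_size < 1 or set_size > len(regulators_sorted):
        raise ValueError(
            f"set_size must be in [1, {len(regulators_sorted)}], got {set_size}"
        )
    rng = np.random.default_rng(seed)
    rows = []
    for d in range(n_draws):
        draw = sorted(rng.choice(regulators_sorted, size=set_size, replace=False))
        gs = GeneSet(name=f"draw{d}", members=frozenset(draw))
        _, ri = classify_collection(
            collection, gs, reference=reference, n_components=n_components, k=k
        )
        rows.append((d, ";".join(draw), ri))
    return pd.DataFrame(rows, columns=["draw", "tfs", "rand_index"])
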