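"""Housekeeping vs cell-type-specific interaction calculus.

An edge present in every network of a collection is a housekeeping (HK)
interaction; an edge present in exactly one network is specific to that cell
type.  The leave-k-out curve measures how stable the common-interaction count
is when k networks are dropped, guarding the HK definition against single
noisy networks.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping

import pandas as pd

from .network_io import DirectedNetwork, Edge, NetworkCollection


@dataclass(frozen=True)
class ConservationTable:
    """Per-edge occurrence counts across a collection.

    ``membership`` stores, per edge, a bitmask over network indices (bit i set
    iff network i contains the edge); ``occurrence`` is its popcount.
    """

    occurrence: Mapping[Edge, int]
    n_networks: int
    network_names: tuple[str, ...]
    membership: Mapping[Edge, int] = field(repr=False, default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [(u, v, c) for (u, v), c in sorted(self.occurrence.items())]
        return pd.DataFrame(rows, columns=["regulator", "target", "count"])


def build_conservation(collection: NetworkCollection) -> ConservationTable:
    """Count, for every edge in the union, how many member networks contain it."""
    if len(collection) == 0:
        raise ValueError("empty collection")
    masks: dict[Edge, int] = {}
    for i, net in enumerate(collection):
        bit = 1 << i
        for e in net.edges:
            masks[e] = masks.get(e, 0) | bit
    occurrence = {e: m.bit_count() for e, m in masks.items()}
    return ConservationTable(
        occurrence=occurrence,
        n_networks=len(collection),
        network_names=tuple(collection.names),
        membership=masks,
    )


def housekeeping_edges(table: ConservationTable) -> frozenset[Edge]:
    """Edges present in all ``n_networks`` networks."""
    n = table.n_networks
    return frozenset(e for e, c in table.occurrence.items() if c == n)


def specific_edges(table: ConservationTable, network: str) -> frozenset[Edge]:
    """Edges present in the named network and nowhere else."""
    try:
        idx = table.network_names.index(network)
    except ValueError:
        raise KeyError(f"unknown network {network!r}") from None
    bit = 1 << idx
    return frozenset(
        e for e, m in table.membership.items() if m == bit
    )


def specific_subnetwork(collection: NetworkCollection, network: str) -> DirectedNetwork:
    """The network induced by the named member's specific edges (nodes are
    the endpoints of those edges)."""
    table = build_conservation(collection)
    spec = specific_edges(table, network)
    if not spec:
        raise ValueError(f"network {network!r} has no specific interactions")
    return DirectedNetwork.from_edges(name=f"{network}_specific", edges=spec)


def _common_count(table: ConservationTable, retained_mask: int) -> int:
    return sum(1 for m in table.membership.values() if m & retained_mask == retained_mask)


def leave_k_out_curve(
    collection: NetworkCollection,
    k_max: int = 5,
    n_subsets: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Common-interaction counts after leaving k networks out, k = 0..k_max.

    For each k, all C(n, k) left-out subsets are enumerated when their number
    does not exceed ``n_subsets``; otherwise ``n_subsets`` distinct subsets
    are sampled uniformly without replacement using ``seed``.  Returns a
    table with columns k, n_subsets_used, mean, min, max.
    """
    n = len(collection)
    if not 0 <= k_max < n:
        raise ValueError(f"k_max must satisfy 0 <= k_max < {n}, got {k_max}")
    if n_subsets < 1:
        raise ValueError("n_subsets must be >= 1")
    table = build_conservation(collection)
    full_mask = (1 << n) - 1
    rng = random.Random(seed)
    rows = []
    for k in range(k_max + 1):
        total = math.comb(n, k)
        if total <= n_subsets:
            subsets = list(combinations(range(n), k))
        else:
            chosen: set[tuple[int, ...]] = set()
            while len(chosen) < n_subsets:
                chosen.add(tuple(sorted(rng.sample(range(n), k))))
            subsets = sorted(chosen)
        counts = []
        for left_out in subsets:
            retained = full_mask
            for i in left_out:
                retained &= ~(1 << i)
            counts.append(_common_count(table, retained))
        rows.append(
            (k, len(subsets), sum(counts) / len(counts), min(counts), max(counts))
        )
    return pd.DataFrame(rows, columns=["k", "n_subsets_used", "mean", "min", "max"])
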