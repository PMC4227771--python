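"""Regulatory complex-target modules and HK-dense protein complexes.

A complex-target module pairs >= 2 TFs from one protein complex (the
regulator set R) with the full set B of TFs that every member of R regulates
through cell-type-specific interactions only.  Modules are maximal bicliques
of the per-complex regulator -> specific-target relation under concept
closure: B is the exact common-target set of R, and R is the full set of
present complex members whose specific targets cover B.  Without maximality
every regulator sub-pair would count as its own module and the module count
would be ill-defined.

A complex is HK-dense when its members, restricted to the housekeeping
interaction network, are wired by a sufficiently dense and weakly connected
set of HK edges.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import pandas as pd

from .network_io import ComplexCatalog, DirectedNetwork, Edge


@dataclass(frozen=True)
class ComplexTargetModule:
    complex_id: str
    regulators: frozenset[str]
    targets: frozenset[str]
    evidence: frozenset[Edge]

    def __post_init__(self) -> None:
        if len(self.regulators) < 2:
            raise ValueError("a module needs >= 2 regulators")
        if not self.targets:
            raise ValueError("a module needs >= 1 target")


def _targets_of(net: DirectedNetwork) -> dict[str, frozenset[str]]:
    adj: dict[str, set[str]] = {}
    for u, v in net.edges:
        adj.setdefault(u, set()).add(v)
    return {u: frozenset(vs) for u, vs in adj.items()}


def _closed_target_sets(target_sets: list[frozenset[str]]) -> set[frozenset[str]]:
    """All non-empty intersections of subsets of the given family (concept
    closure under intersection)."""
    closed: set[frozenset[str]] = set(t for t in target_sets if t)
    frontier = set(closed)
    while frontier:
        new: set[frozenset[str]] = set()
        for b in frontier:
            for t in target_sets:
                inter = b & t
                if inter and inter not in closed:
                    new.add(inter)
        closed |= new
        frontier = new
    return closed


def complex_target_modules(
    specific_net: DirectedNetwork,
    catalog: ComplexCatalog,
    min_regulators: int = 2,
    mode: str = "maximal",
) -> list[ComplexTargetModule]:
    """Enumerate complex-target modules over a specific-interaction network.

    ``mode='maximal'`` (default) reports one maximal biclique per closed
    common-target set; ``mode='all'`` reports every regulator subset of size
    >= ``min_regulators`` with a non-empty common target set.  Results are
    sorted by (complex_id, |R| descending, lexicographic regulators).
    """
    if len(catalog) == 0:
        raise ValueError("empty complex catalog")
    if mode not in ("maximal", "all"):
        raise ValueError(f"mode must be 'maximal' or 'all', got {mode!r}")
    targets_of = _targets_of(specific_net)
    modules: dict[tuple[str, frozenset[str], frozenset[str]], ComplexTargetModule] = {}
    for cid, members in catalog.items():
        present = sorted(m for m in members if m in targets_of)
        if len(present) < min_regulators:
            continue
        if mode == "all":
            if len(present) > 20:
                raise ValueError(
                    f"complex {cid!r}: {len(present)} present members is too "
                    "large for exhaustive mode"
                )
            candidates = []
            for r in range(min_regulators, len(present) + 1):
                for R in combinations(present, r):
                    B = frozenset.intersection(*(targets_of[m] for m in R))
                    if B:
                        candidates.append((frozenset(R), B))
        else:
            fam = [targets_of[m] for m in present]
            candidates = []
            for B in _closed_target_sets(fam):
                R = frozenset(m for m in present if targets_of[m] >= B)
                if len(R) >= min_regulators and frozenset.intersection(
                    *(targets_of[m] for m in R)
                ) == B:
                    candidates.append((R, B))
        for R, B in candidates:
            key = (cid, R, B)
            if key not in modules:
                modules[key] = ComplexTargetModule(
                    complex_id=cid,
                    regulators=R,
                    targets=B,
                    evidence=frozenset((r, b) for r in R for b in B),
                )
    return sorted(
        modules.values(),
        key=lambda m: (m.complex_id, -len(m.regulators), sorted(m.regulators), sorted(m.targets)),
    )


def modules_to_frame(modules: list[ComplexTargetModule]) -> pd.DataFrame:
    rows = [
        (
            m.complex_id,
            ";".join(sorted(m.regulators)),
            ";".join(sorted(m.targets)),
            len(m.evidence),
        )
        for m in modules
    ]
    return pd.DataFrame(rows, columns=["complex_id", "regulators", "targets", "n_edges"])


def hk_dense_complexes(
    hk_net: DirectedNetwork,
    catalog: ComplexCatalog,
    min_members: int = 3,
    min_density: float = 0.5,
) -> pd.DataFrame:
    """Complexes whose members are densely wired by housekeeping edges.

    For every complex with m >= ``min_members`` members present in the HK
    network, density = (HK edges among members, ordered pairs, self-loops
    excluded) / (m * (m - 1)).  Complexes pass when density >=
    ``min_density`` and the HK subgraph among members is weakly connected.
    Returns a table (complex_id, n_members, n_hk_edges, density) sorted by
    descending density.
    """
    if not 0 < min_density <= 1:
        raise ValueError("min_density must be in (0, 1]")
    rows = []
    for cid, members in catalog.items():
        present = members & hk_net.nodes
        m = len(present)
        if m < min_members:
            continue
        internal = [
            (u, v) for (u, v) in hk_net.edges if u != v and u in present and v in present
        ]
        density = len(internal) / (m * (m - 1))
        if density < min_density:
            continue
        sub = nx.DiGraph()
        sub.add_nodes_from(present)
        sub.add_edges_from(internal)
        if not nx.is_weakly_connected(sub):
            continue
        rows.append((cid, m, len(internal), density))
    df = pd.DataFrame(rows, columns=["complex_id", "n_members", "n_hk_edges", "density"])
    return df.sort_values(["density", "complex_id"], ascending=[False, True]).reset_index(
        drop=True
    )
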