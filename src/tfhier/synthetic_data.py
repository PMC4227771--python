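"""Seed-deterministic generators of network collections, expression matrices
and complex catalogs with planted ground truth.

The collection generator emulates the structure of a set of per-cell-type TF
regulatory networks: a shared housekeeping backbone present in every network,
a large strongly connected core with small top and bottom fringes, per-network
unique (specific) edges, and class-structured wiring differences (a marker TF
set wired to class-specific target sets, plus per-class shared edges).  The
construction is such that every planted structure is recovered exactly by the
corresponding analysis stage at zero noise:

* the core is made strongly connected by a random Hamiltonian cycle, top
  nodes only emit and bottom nodes only receive, so vertex sorting recovers
  the planted layers in every network;
* backbone, marker, class and specific edge pools are disjoint by
  construction, so the housekeeping and specific edge sets are unambiguous;
* specific pools exclude pairs whose source is a marker TF, so the wiring of
  the marker set is purely class-determined and classes are separable.

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .conservation import build_conservation, specific_edges
from .network_io import (
    ComplexCatalog,
    DirectedNetwork,
    Edge,
    ExpressionMatrix,
    GeneSet,
    NetworkCollection,
)

#: class layout of the 41-cell-type study: eight classes with these sizes
STUDY_CLASS_SIZES: dict[str, int] = {
    "blood": 7,
    "cancer": 2,
    "endothelia": 4,
    "epithelia": 6,
    "ESC": 1,
    "fetal": 3,
    "stroma": 14,
    "viscera": 4,
}


@dataclass
class SyntheticTruth:
    """Planted ground truth attached to generator output."""

    layer: dict[str, str] = field(default_factory=dict)
    backbone: frozenset[Edge] = frozenset()
    specific: dict[str, frozenset[Edge]] = field(default_factory=dict)
    class_label: dict[str, str] = field(default_factory=dict)
    marker_set: GeneSet | None = None
    class_targets: dict[str, frozenset[str]] = field(default_factory=dict)
    class_edges: dict[str, frozenset[Edge]] = field(default_factory=dict)
    stable_genes: frozenset[str] = frozenset()
    variable_genes: frozenset[str] = frozenset()
    modules: list[tuple[str, frozenset[str], frozenset[str]]] = field(default_factory=list)


def _default_class_sizes(n_networks: int) -> dict[str, int]:
    if n_networks == sum(STUDY_CLASS_SIZES.values()):
        return dict(STUDY_CLASS_SIZES)
    names = list(STUDY_CLASS_SIZES)
    k = min(len(names), n_networks)
    sizes = {names[i]: n_networks // k + (1 if i < n_networks % k else 0) for i in range(k)}
    return {n: s for n, s in sizes.items() if s > 0}


def generate_collection(
    n_tfs: int = 475,
    n_networks: int = 41,
    class_sizes: dict[str, int] | list[int] | None = None,
    layer_fractions: tuple[float, float, float] = (0.23, 0.67, 0.10),
    core_extra_edge_prob: float = 0.10,
    n_backbone: int | None = None,
    n_specific_per_network: int = 275,
    marker_set_size: int = 7,
    n_class_targets: int = 8,
    class_target_overlap: float = 0.0,
    n_class_edges: int = 100,
    seed: int = 0,
) -> tuple[NetworkCollection, SyntheticTruth]:
    """Generate a collection of directed TF networks with planted structure.

    Parameters mirror the geometry of the 41-network study at their
    defaults (475 TFs, ~11k edges per network, eight classes).  ``n_backbone``
    is the total housekeeping backbone size; ``None`` uses the structural
    backbone alone (core cycle, top/bottom attachments and the dense-core
    extra edges drawn with ``core_extra_edge_prob``).  ``class_target_overlap``
    is the fraction of each class's marker-target set shared by all classes
    (0 = perfectly separable classes).
    """
    f_top, f_core, f_bottom = layer_fractions
    if abs(f_top + f_core + f_bottom - 1.0) > 1e-9:
        raise ValueError("layer fractions must sum to 1")
    if not 0.0 <= class_target_overlap <= 1.0:
        raise ValueError("class_target_overlap must be in [0, 1]")
    if class_sizes is None:
        class_sizes = _default_class_sizes(n_networks)
    elif isinstance(class_sizes, (list, tuple)):
        class_sizes = {f"class{i + 1}": s for i, s in enumerate(class_sizes)}
    if sum(class_sizes.values()) != n_networks:
        raise ValueError("class sizes must sum to n_networks")

    rng = np.random.default_rng(seed)
    nodes = [f"TF{i:04d}" for i in range(1, n_tfs + 1)]
    perm = [nodes[i] for i in rng.permutation(n_tfs)]
    n_top = round(f_top * n_tfs)
    n_bottom = round(f_bottom * n_tfs)
    n_core = n_tfs - n_top - n_bottom
    if n_core < 2:
        raise ValueError("need at least 2 core TFs")
    top = perm[:n_top]
    core = perm[n_top : n_top + n_core]
    bottom = perm[n_top + n_core :]
    layer = {n: "top" for n in top}
    layer.update({n: "core" for n in core})
    layer.update({n: "bottom" for n in bottom})

    # structural backbone: Hamiltonian cycle over the core, one out-edge per
    # top node into the core, one in-edge per bottom node from the core,
    # plus independent extra core->core edges
    cyc = [core[i] for i in rng.permutation(n_core)]
    structural: set[Edge] = {(cyc[i], cyc[(i + 1) % n_core]) for i in range(n_core)}
    for t in top:
        structural.add((t, core[rng.integers(n_core)]))
    for b in bottom:
        structural.add((core[rng.integers(n_core)], b))
    if core_extra_edge_prob > 0:
        mask = rng.random((n_core, n_core)) < core_extra_edge_prob
        np.fill_diagonal(mask, False)
        for i, j in np.argwhere(mask):
            structural.add((core[i], core[j]))

    sources = top + core
    targets_all = core + bottom
    admissible = [(u, v) for u in sources for v in targets_all if u != v]
    order = rng.permutation(len(admissible))
    used: set[Edge] = set(structural)
    pointer = 0

    def take(n_needed: int, ok) -> list[Edge]:
        nonlocal pointer
        out: list[Edge] = []
        while len(out) < n_needed and pointer < len(order):
            pair = admissible[order[pointer]]
            pointer += 1
            if pair in used or not ok(pair):
                continue
            used.add(pair)
            out.append(pair)
        if len(out) < n_needed:
            raise ValueError(
                "infeasible edge budget: admissible pair pool exhausted "
                f"(needed {n_needed}, found {len(out)})"
            )
        return out

    backbone: set[Edge] = set(structural)
    if n_backbone is not None:
        if len(structural) > n_backbone:
            raise ValueError(
                f"structural backbone already has {len(structural)} edges, "
                f"more than n_backbone={n_backbone}; lower core_extra_edge_prob"
            )
        backbone |= set(take(n_backbone - len(structural), lambda p: True))

    # marker TF set A and class-specific target sets
    class_names = list(class_sizes)
    core_perm = [core[i] for i in rng.permutation(n_core)]
    if marker_set_size > n_core:
        raise ValueError("marker_set_size exceeds core size")
    marker_tfs = core_perm[:marker_set_size]
    n_shared = round(class_target_overlap * n_class_targets)
    n_unique = n_class_targets - n_shared
    target_pool = core_perm[marker_set_size:]
    needed = n_shared + n_unique * len(class_names)
    if needed > len(target_pool):
        raise ValueError("not enough core TFs for the requested class target sets")
    shared_targets = target_pool[:n_shared]
    class_targets: dict[str, list[str]] = {}
    pos = n_shared
    for cls in class_names:
        class_targets[cls] = shared_targets + target_pool[pos : pos + n_unique]
        pos += n_unique
    marker_pairs: dict[str, set[Edge]] = {}
    all_marker_pairs: set[Edge] = set()
    for cls in class_names:
        pairs = {
            (a, t) for a in marker_tfs for t in class_targets[cls] if a != t
        } - backbone
        marker_pairs[cls] = pairs
        all_marker_pairs |= pairs
    used |= all_marker_pairs
    shared_marker_pairs = {
        (a, t) for a in marker_tfs for t in shared_targets if a != t
    } - backbone

    marker_set = set(marker_tfs)
    not_marker_source = lambda p: p[0] not in marker_set  # noqa: E731

    class_edge_sets: dict[str, set[Edge]] = {
        cls: set(take(n_class_edges, not_marker_source)) for cls in class_names
    }
    specific_sets: dict[str, set[Edge]] = {}
    names_by_class: dict[str, list[str]] = {}
    for cls in class_names:
        names_by_class[cls] = [f"{cls}{i + 1:02d}" for i in range(class_sizes[cls])]
        for name in names_by_class[cls]:
            specific_sets[name] = set(take(n_specific_per_network, not_marker_source))

    networks = []
    labels: dict[str, str] = {}
    truth_specific: dict[str, frozenset[Edge]] = {}
    for cls in class_names:
        for name in names_by_class[cls]:
            edges = backbone | marker_pairs[cls] | class_edge_sets[cls] | specific_sets[name]
            networks.append(
                DirectedNetwork.from_edges(name, edges, extra_nodes=nodes)
            )
            labels[name] = cls
            spec = set(specific_sets[name])
            if class_sizes[cls] == 1:
                # a singleton class's marker/class edges occur in one network
                spec |= (marker_pairs[cls] - shared_marker_pairs) | class_edge_sets[cls]
            truth_specific[name] = frozenset(spec)

    collection = NetworkCollection(networks=tuple(networks), class_label=labels)
    truth = SyntheticTruth(
        layer=layer,
        backbone=frozenset(backbone | shared_marker_pairs),
        specific=truth_specific,
        class_label=labels,
        marker_set=GeneSet(name="markers", members=frozenset(marker_tfs)),
        class_targets={c: frozenset(ts) for c, ts in class_targets.items()},
        class_edges={c: frozenset(es) for c, es in class_edge_sets.items()},
    )
    return collection, truth


def generate_expression(
    n_genes: int = 200,
    n_tissues: int = 79,
    stable_fraction: float = 0.5,
    noise_sd: float = 0.05,
    concentration: float = 0.05,
    seed: int = 0,
    genes: list[str] | None = None,
    stable_genes: set[str] | None = None,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Generate a gene x tissue expression matrix with planted stable and
    tissue-restricted genes.

    Stable genes have one base level with multiplicative log-normal noise of
    standard deviation ``noise_sd`` (exactly constant at 0).  Variable genes
    draw tissue weights from a symmetric Dirichlet with the given
    ``concentration``; small values concentrate mass in few tissues.
    Explicit ``stable_genes`` override ``stable_fraction``.
    """
    import pandas as pd

    if not 0.0 <= stable_fraction <= 1.0:
        raise ValueError("stable_fraction must be in [0, 1]")
    if noise_sd < 0 or concentration <= 0:
        raise ValueError("noise_sd must be >= 0 and concentration > 0")
    rng = np.random.default_rng(seed)
    if genes is None:
        genes = [f"G{i:04d}" for i in range(1, n_genes + 1)]
    else:
        genes = list(genes)
        n_genes = len(genes)
    if stable_genes is None:
        n_stable = round(stable_fraction * n_genes)
        perm = rng.permutation(n_genes)
        stable = {genes[i] for i in perm[:n_stable]}
    else:
        stable = set(stable_genes) & set(genes)
    tissues = [f"tissue{j:02d}" for j in range(1, n_tissues + 1)]
    values = np.empty((n_genes, n_tissues))
    for i, g in enumerate(genes):
        if g in stable:
            base = rng.uniform(50.0, 500.0)
            if noise_sd == 0:
                values[i] = base
            else:
                values[i] = base * np.exp(rng.normal(0.0, noise_sd, n_tissues))
        else:
            gamma = rng.gamma(concentration, 1.0, n_tissues)
            total = gamma.sum()
            if total == 0:  # extreme-concentration underflow: one-hot row
                w = np.zeros(n_tissues)
                w[rng.integers(n_tissues)] = 1.0
            else:
                w = gamma / total
            values[i] = rng.uniform(50.0, 500.0) * n_tissues * w
    expr = ExpressionMatrix(data=pd.DataFrame(values, index=genes, columns=tissues))
    truth = SyntheticTruth(
        stable_genes=frozenset(stable),
        variable_genes=frozenset(genes) - frozenset(stable),
    )
    return expr, truth


def generate_complex_catalog(
    collection: NetworkCollection,
    specific_name: str,
    n_complexes: int = 20,
    size_range: tuple[int, int] = (3, 6),
    n_planted_modules: int = 10,
    targets_per_module: int = 3,
    regulators_per_module: int = 2,
    seed: int = 0,
    max_tries: int = 500,
) -> tuple[ComplexCatalog, NetworkCollection, SyntheticTruth]:
    """Generate a protein-complex catalog with planted complex-target
    modules wired into one designated network.

    For each planted module a regulator pair/group R inside one complex and
    a target set B are chosen, and the R x B edges are injected into the
    designated network only, guaranteeing they are specific to it.  Complex
    membership is screened so that no accidental co-targeting (two members
    of one complex sharing a specific target outside a planted module)
    occurs.  Returns the catalog, the modified collection and the truth.
    """
    if n_planted_modules > n_complexes:
        raise ValueError("cannot plant more modules than complexes")
    if regulators_per_module < 2:
        raise ValueError("a planted module needs >= 2 regulators")
    designated = collection.get(specific_name)
    rng = np.random.default_rng(seed)

    out_deg = designated.out_degrees()
    in_deg = designated.in_degrees()
    cand_reg = sorted(n for n in designated.nodes if out_deg[n] > 0)
    cand_tgt = sorted(n for n in designated.nodes if in_deg[n] > 0)
    union_edges = collection.union_edges()

    # pre-injection specific-target relation, for screening planted regulators
    table0 = build_conservation(collection)
    spec0 = specific_edges(table0, specific_name)
    t0: dict[str, set[str]] = {}
    for u, v in spec0:
        t0.setdefault(u, set()).add(v)

    reg_pool = [cand_reg[i] for i in rng.permutation(len(cand_reg))]
    planted_regs: list[list[str]] = []
    group: list[str] = []
    for r in reg_pool:
        if any(t0.get(r, set()) & t0.get(o, set()) for o in group):
            continue
        group.append(r)
        if len(group) == regulators_per_module:
            planted_regs.append(group)
            group = []
        if len(planted_regs) == n_planted_modules:
            break
    if len(planted_regs) < n_planted_modules:
        raise ValueError("not enough independent regulators to plant the modules")
    used_nodes = {r for g in planted_regs for r in g}

    tgt_pool = [t for t in (cand_tgt[i] for i in rng.permutation(len(cand_tgt))) if t not in used_nodes]
    planted: list[tuple[list[str], list[str]]] = []
    for R in planted_regs:
        # targets may be shared across modules (they live in different
        # complexes); each module shuffles its own view of the pool
        view = [tgt_pool[i] for i in rng.permutation(len(tgt_pool))]
        B: list[str] = []
        for t in view:
            if len(B) == targets_per_module:
                break
            if t in B or any((r, t) in union_edges or r == t for r in R):
                continue
            B.append(t)
        if len(B) < targets_per_module:
            raise ValueError("collision with existing edges exhausts admissible targets")
        planted.append((R, B))

    injected = {(r, t) for R, B in planted for r in R for t in B}
    new_designated = DirectedNetwork.from_edges(
        designated.name, designated.edges | injected, extra_nodes=designated.nodes
    )
    new_collection = collection.replace_network(new_designated)

    # post-injection specific-target relation, for membership screening
    table1 = build_conservation(new_collection)
    spec1 = specific_edges(table1, specific_name)
    t1: dict[str, frozenset[str]] = {}
    tmp: dict[str, set[str]] = {}
    for u, v in spec1:
        tmp.setdefault(u, set()).add(v)
    t1 = {u: frozenset(v) for u, v in tmp.items()}

    def common(a: str, b: str) -> frozenset[str]:
        return t1.get(a, frozenset()) & t1.get(b, frozenset())

    lo, hi = size_range
    all_nodes = new_collection.union_nodes()
    complexes: list[frozenset[str]] = []
    truth_modules: list[tuple[frozenset[str], frozenset[str]]] = []

    def fill_members(base: list[str], size: int, forbidden_pairs_base: frozenset[str]) -> frozenset[str]:
        """Extend ``base`` to ``size`` members such that no member pair
        outside the planted regulator group co-targets specifically."""
        for _ in range(max_tries):
            extra = [
                all_nodes[i]
                for i in rng.choice(len(all_nodes), size=size - len(base), replace=False)
            ]
            members = base + extra
            if len(set(members)) < size:
                continue
            ok = True
            for i, a in enumerate(members):
                for b in members[i + 1 :]:
                    if a in forbidden_pairs_base and b in forbidden_pairs_base:
                        continue  # planted pair, checked separately
                    if common(a, b):
                        ok = False
                        break
                if not ok:
                    break
            if ok:
                return frozenset(members)
        raise ValueError("could not assemble a complex without accidental co-targeting")

    for R, B in planted:
        size = int(rng.integers(max(lo, len(R)), hi + 1))
        Bset = frozenset(B)
        for i, r1 in enumerate(R):
            for r2 in R[i + 1 :]:
                if common(r1, r2) != Bset:
                    raise ValueError("planted regulators share unplanned specific targets")
        complexes.append(fill_members(list(R), size, frozenset(R)))
        truth_modules.append((frozenset(R), Bset))
    for _ in range(n_complexes - n_planted_modules):
        size = int(rng.integers(lo, hi + 1))
        complexes.append(fill_members([], size, frozenset()))

    id_order = rng.permutation(n_complexes)
    ids = [f"HC{1000 + i:04d}" for i in range(n_complexes)]
    catalog: dict[str, frozenset[str]] = {}
    modules: list[tuple[str, frozenset[str], frozenset[str]]] = []
    for slot, cx_idx in enumerate(id_order):
        catalog[ids[slot]] = complexes[cx_idx]
        if cx_idx < len(truth_modules):
            R, B = truth_modules[cx_idx]
            modules.append((ids[slot], R, B))
    modules.sort(key=lambda m: m[0])
    # the injected module edges are, by construction, specific to the
    # designated network; report them so callers can extend its truth
    truth = SyntheticTruth(
        modules=modules, specific={specific_name: frozenset(injected)}
    )
    return ComplexCatalog(complexes=catalog), new_collection, truth


def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    """Serialise planted ground truth as YAML."""
    doc = {
        "layer": dict(sorted(truth.layer.items())),
        "backbone": sorted(list(e) for e in truth.backbone),
        "specific": {
            name: sorted(list(e) for e in edges)
            for name, edges in sorted(truth.specific.items())
        },
        "class_label": dict(sorted(truth.class_label.items())),
        "marker_set": sorted(truth.marker_set.members) if truth.marker_set else [],
        "class_targets": {c: sorted(t) for c, t in sorted(truth.class_targets.items())},
        "class_edges": {
            c: sorted(list(e) for e in es) for c, es in sorted(truth.class_edges.items())
        },
        "stable_genes": sorted(truth.stable_genes),
        "variable_genes": sorted(truth.variable_genes),
        "modules": [
            {"complex_id": cid, "regulators": sorted(R), "targets": sorted(B)}
            for cid, R, B in truth.modules
        ],
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
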