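"""Readers, writers and validated in-memory model for TF regulatory network data.

The analyses in this package consume five plain-text formats:

* network: 2-column TSV ``regulator TAB target``; ``#`` comment lines; an
  optional single header line whose first two fields are ``regulator``/``target``
  (case-insensitive) is skipped.
* collection manifest: 3-column TSV ``name TAB class_label TAB path`` with a
  header row; paths are resolved relative to the manifest.
* gene set: one symbol per line.
* protein-complex catalog: TSV ``complex_id TAB member;member;...``.
* expression matrix: TSV, first column gene symbol, header row of tissue names.

Symbols are compared case-sensitively after stripping surrounding whitespace;
no alias resolution is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

Edge = tuple[str, str]


class FormatError(ValueError):
    """Raised when an input file violates its documented format."""


@dataclass(frozen=True)
class DirectedNetwork:
    """A named directed graph of TF symbols (regulator -> target).

    Edges form a set (no duplicates); self-loops are permitted and represent
    autoregulation.
    """

    name: str
    nodes: frozenset[str]
    edges: frozenset[Edge]

    def __post_init__(self) -> None:
        for u, v in self.edges:
            if u not in self.nodes or v not in self.nodes:
                raise ValueError(
                    f"network {self.name!r}: edge ({u!r}, {v!r}) has an "
                    "endpoint outside the node set"
                )

    @classmethod
    def from_edges(
        cls,
        name: str,
        edges: Iterable[Edge],
        extra_nodes: Iterable[str] = (),
    ) -> "DirectedNetwork":
        """Build a network whose node set is the union of edge endpoints
        plus any ``extra_nodes`` (nodes without incident edges)."""
        edge_set = frozenset((str(u), str(v)) for u, v in edges)
        nodes = frozenset(n for e in edge_set for n in e) | frozenset(
            str(n) for n in extra_nodes
        )
        return cls(name=name, nodes=nodes, edges=edge_set)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def sorted_nodes(self) -> list[str]:
        return sorted(self.nodes)

    def to_networkx(self, drop_self_loops: bool = False) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        if drop_self_loops:
            g.add_edges_from((u, v) for u, v in self.edges if u != v)
        else:
            g.add_edges_from(self.edges)
        return g

    def out_degrees(self) -> dict[str, int]:
        """Out-degree per node; a self-loop counts once."""
        deg = dict.fromkeys(self.nodes, 0)
        for u, _ in self.edges:
            deg[u] += 1
        return deg

    def in_degrees(self) -> dict[str, int]:
        """In-degree per node; a self-loop counts once."""
        deg = dict.fromkeys(self.nodes, 0)
        for _, v in self.edges:
            deg[v] += 1
        return deg

    def total_degrees(self) -> dict[str, int]:
        """in + out degree; a self-loop therefore counts twice."""
        out = self.out_degrees()
        inn = self.in_degrees()
        return {n: out[n] + inn[n] for n in self.nodes}


@dataclass(frozen=True)
class NetworkCollection:
    """An ordered set of per-cell-type networks with class labels."""

    networks: tuple[DirectedNetwork, ...]
    class_label: Mapping[str, str]

    def __post_init__(self) -> None:
        names = [n.name for n in self.networks]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate network names: {dupes}")
        missing = [n for n in names if n not in self.class_label]
        if missing:
            raise ValueError(f"networks without a class label: {missing}")

    def __iter__(self) -> Iterator[DirectedNetwork]:
        return iter(self.networks)

    def __len__(self) -> int:
        return len(self.networks)

    @property
    def names(self) -> list[str]:
        return [n.name for n in self.networks]

    def get(self, name: str) -> DirectedNetwork:
        for net in self.networks:
            if net.name == name:
                return net
        raise KeyError(f"no network named {name!r} in collection")

    def union_nodes(self) -> list[str]:
        """Deterministic (lexicographic) union of all node sets."""
        out: set[str] = set()
        for net in self.networks:
            out |= net.nodes
        return sorted(out)

    def union_edges(self) -> frozenset[Edge]:
        out: set[Edge] = set()
        for net in self.networks:
            out |= net.edges
        return frozenset(out)

    def replace_network(self, net: DirectedNetwork) -> "NetworkCollection":
        """Return a new collection with the same-named member replaced."""
        if net.name not in self.names:
            raise KeyError(f"no network named {net.name!r} in collection")
        nets = tuple(net if m.name == net.name else m for m in self.networks)
        return NetworkCollection(networks=nets, class_label=dict(self.class_label))


@dataclass(frozen=True)
class GeneSet:
    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.members


@dataclass(frozen=True)
class ComplexCatalog:
    """Protein-complex catalog: complex id -> member symbols."""

    complexes: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        for cid, members in self.complexes.items():
            if not members:
                raise ValueError(f"complex {cid!r} has no members")

    def __len__(self) -> int:
        return len(self.complexes)

    def items(self):
        return self.complexes.items()


@dataclass(frozen=True)
class ExpressionMatrix:
    """Gene x tissue non-negative expression levels.

    ``degenerate_genes`` lists all-zero rows; these carry no tissue
    distribution and are excluded from entropy analyses.
    """

    data: pd.DataFrame
    degenerate_genes: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        values = self.data.to_numpy(dtype=float)
        if (values < 0).any():
            g, t = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative expression value for gene {self.data.index[g]!r} "
                f"in tissue {self.data.columns[t]!r}"
            )
        zero_rows = frozenset(self.data.index[(values.sum(axis=1) == 0)])
        object.__setattr__(self, "degenerate_genes", zero_rows)

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def tissues(self) -> list[str]:
        return list(self.data.columns)

    def row(self, gene: str) -> np.ndarray:
        return self.data.loc[gene].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# readers / writers


def _data_lines(path: Path) -> Iterator[tuple[int, str]]:
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line


def read_network(path: str | Path, name: str | None = None) -> DirectedNetwork:
    """Read a 2-column TSV edge list into a :class:`DirectedNetwork`.

    Duplicate edge lines collapse to a single edge (logged); the node set is
    the union of endpoints.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    name = name if name is not None else path.stem
    edges: list[Edge] = []
    first = True
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 2:
            raise FormatError(f"{path}:{lineno}: expected >= 2 tab-separated fields")
        u, v = fields[0].strip(), fields[1].strip()
        if first:
            first = False
            if u.lower() == "regulator" and v.lower() == "target":
                continue
        if not u or not v:
            raise FormatError(f"{path}:{lineno}: empty regulator or target symbol")
        edges.append((u, v))
    if not edges:
        raise FormatError(f"{path}: empty network (no edge lines)")
    unique = set(edges)
    n_dupes = len(edges) - len(unique)
    if n_dupes:
        logger.info("%s: collapsed %d duplicate edge line(s)", path, n_dupes)
    return DirectedNetwork.from_edges(name=name, edges=unique)


def write_network(net: DirectedNetwork, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("regulator\ttarget\n")
        for u, v in sorted(net.edges):
            fh.write(f"{u}\t{v}\n")
        # isolated nodes survive a round trip as degenerate self-referential
        # comment records would be ambiguous; they are listed as comments
        isolated = sorted(net.nodes - {n for e in net.edges for n in e})
        for n in isolated:
            fh.write(f"# node\t{n}\n")


def _read_isolated_nodes(path: Path) -> list[str]:
    out = []
    with path.open("r", encoding="utf-8") as fh:
        for raw in fh:
            line = raw.strip()
            if line.startswith("# node\t"):
                out.append(line.split("\t", 1)[1].strip())
    return out


def read_network_with_isolated(path: str | Path, name: str | None = None) -> DirectedNetwork:
    """Read a network preserving ``# node`` records written by
    :func:`write_network` for edge-free nodes."""
    path = Path(path)
    net = read_network(path, name=name)
    extra = _read_isolated_nodes(path)
    if not extra:
        return net
    return DirectedNetwork.from_edges(net.name, net.edges, extra_nodes=set(net.nodes) | set(extra))


def read_collection(manifest_path: str | Path) -> NetworkCollection:
    """Read a collection manifest (TSV: name, class_label, path) and all
    referenced networks, preserving manifest order."""
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise FileNotFoundError(manifest_path)
    df = pd.read_csv(manifest_path, sep="\t", dtype=str, comment="#")
    required = {"name", "class_label", "path"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"{manifest_path}: manifest must have columns {sorted(required)}"
        )
    if df.empty:
        raise FormatError(f"{manifest_path}: empty manifest")
    if df["name"].duplicated().any():
        dupes = sorted(df.loc[df["name"].duplicated(), "name"])
        raise FormatError(f"{manifest_path}: duplicate network name(s) {dupes}")
    networks = []
    labels = {}
    for _, row in df.iterrows():
        net_path = Path(row["path"])
        if not net_path.is_absolute():
            net_path = manifest_path.parent / net_path
        networks.append(read_network_with_isolated(net_path, name=row["name"]))
        labels[row["name"]] = row["class_label"]
    return NetworkCollection(networks=tuple(networks), class_label=labels)


def write_collection(
    collection: NetworkCollection, directory: str | Path, manifest_name: str = "manifest.tsv"
) -> Path:
    """Write all member networks plus a manifest into ``directory``;
    returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for net in collection:
        fname = f"{net.name}.tsv"
        write_network(net, directory / fname)
        rows.append((net.name, collection.class_label[net.name], fname))
    manifest = directory / manifest_name
    with manifest.open("w", encoding="utf-8") as fh:
        fh.write("name\tclass_label\tpath\n")
        for name, label, fname in rows:
            fh.write(f"{name}\t{label}\t{fname}\n")
    return manifest


def read_gene_set(path: str | Path, name: str | None = None) -> GeneSet:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    members = {line.strip() for _, line in _data_lines(path)}
    members.discard("")
    if not members:
        raise FormatError(f"{path}: empty gene set")
    return GeneSet(name=name if name is not None else path.stem, members=frozenset(members))


def write_gene_set(gene_set: GeneSet, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text("".join(f"{s}\n" for s in sorted(gene_set.members)), encoding="utf-8")


def read_complexes(path: str | Path) -> ComplexCatalog:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    complexes: dict[str, frozenset[str]] = {}
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 2:
            raise FormatError(f"{path}:{lineno}: expected 'complex_id TAB members'")
        cid = fields[0].strip()
        if cid.lower() == "complex_id" and lineno == 1:
            continue
        members = frozenset(m.strip() for m in fields[1].split(";") if m.strip())
        if not members:
            raise FormatError(f"{path}:{lineno}: complex {cid!r} has no members")
        if cid in complexes:
            raise FormatError(f"{path}:{lineno}: duplicate complex id {cid!r}")
        complexes[cid] = members
    if not complexes:
        raise FormatError(f"{path}: empty complex catalog")
    return ComplexCatalog(complexes=complexes)


def write_complexes(catalog: ComplexCatalog, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("complex_id\tmembers\n")
        for cid in sorted(catalog.complexes):
            fh.write(f"{cid}\t{';'.join(sorted(catalog.complexes[cid]))}\n")


def read_expression(path: str | Path) -> ExpressionMatrix:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", index_col=0, comment=None)
    if df.empty:
        raise FormatError(f"{path}: empty expression matrix")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric expression value ({exc})") from exc
    df.index = df.index.astype(str).str.strip()
    df.columns = df.columns.astype(str).str.strip()
    return ExpressionMatrix(data=df)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    expr.data.to_csv(path, sep="\t", index_label="gene")
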