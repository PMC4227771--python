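"""Configuration-driven orchestration of the full analysis.

A run is described by a :class:`RunConfig` (typically loaded from YAML):
either real inputs (a collection manifest plus optional gene sets, complex
catalog and expression matrix) or synthetic-generation parameters, a set of
stage toggles, analysis parameters and a seed.  Every output TSV carries a
provenance header (package version, seed, config hash) so that two runs with
the same config and seed produce identical output trees.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import (
    Partition,
    classify_collection,
    linkage_to_newick,
    pca_project,
    random_tf_set_sweep,
    reference_partition,
    target_feature_matrix,
    nnd_feature_matrix,
    ward_cluster,
)
from .complex_modules import complex_target_modules, hk_dense_complexes, modules_to_frame
from .conservation import (
    build_conservation,
    housekeeping_edges,
    leave_k_out_curve,
    specific_edges,
    specific_subnetwork,
)
from .enrichment_stats import (
    entropy_comparison,
    layer_enrichment_table,
)
from .hierarchy import (
    global_reaching_centrality,
    layer_proportions,
    link_distribution,
    vertex_sort,
)
from .network_io import (
    DirectedNetwork,
    GeneSet,
    NetworkCollection,
    read_collection,
    read_complexes,
    read_expression,
    read_gene_set,
    write_collection,
    write_complexes,
    write_expression,
    write_gene_set,
)
from .synthetic_data import (
    generate_collection,
    generate_complex_catalog,
    generate_expression,
    write_truth,
)

logger = logging.getLogger(__name__)

STAGES = ("hierarchy", "conservation", "classify", "enrich", "entropy", "modules")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class RunConfig:
    """Everything a pipeline run needs; exactly one of ``manifest`` (real
    inputs) or ``synthetic`` (generation parameters) must be set."""

    outdir: Path
    seed: int = 0
    manifest: Path | None = None
    gene_sets: dict[str, Path] = field(default_factory=dict)
    complexes: Path | None = None
    expression: Path | None = None
    marker_set: Path | None = None
    specific_network: str | None = None
    synthetic: dict[str, Any] | None = None
    stages: dict[str, bool] = field(default_factory=dict)
    params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        if (self.manifest is None) == (self.synthetic is None):
            raise ValueError(
                "config must set exactly one of 'manifest' (real inputs) or "
                "'synthetic' (generation parameters)"
            )
        for s in self.stages:
            if s not in STAGES:
                raise ValueError(f"unknown stage {s!r}; known stages: {STAGES}")

    def stage_enabled(self, stage: str) -> bool:
        return self.stages.get(stage, True)

    def param(self, name: str, default: Any) -> Any:
        return self.params.get(name, default)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "RunConfig":
        with Path(path).open("r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        doc.update(overrides)
        for key in ("manifest", "complexes", "expression", "marker_set"):
            if doc.get(key) is not None:
                doc[key] = Path(doc[key])
        if doc.get("gene_sets"):
            doc["gene_sets"] = {k: Path(v) for k, v in doc["gene_sets"].items()}
        return cls(**doc)

    def config_hash(self) -> str:
        # stage toggles are excluded: they select which outputs exist but
        # never change another stage's numeric content
        doc = {
            "seed": self.seed,
            "manifest": str(self.manifest),
            "synthetic": self.synthetic,
            "params": self.params,
        }
        return hashlib.sha256(
            yaml.safe_dump(doc, sort_keys=True).encode()
        ).hexdigest()[:12]


def _write_tsv(df: pd.DataFrame, path: Path, config: RunConfig) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"# tfhier {__version__}\n")
        fh.write(f"# seed: {config.seed}\n")
        fh.write(f"# config: {config.config_hash()}\n")
        df.to_csv(fh, sep="\t", index=False)
    return path


def _stage_seed(config: RunConfig, stage: str) -> int:
    # independent, stable per-stage randomness: disabling one stage never
    # shifts another stage's stream
    digest = hashlib.sha256(f"{config.seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _load_inputs(config: RunConfig):
    """Load or generate the collection and side inputs.

    Returns (collection, gene_sets, marker_set, catalog, expression,
    specific_network_name, truth-or-None).
    """
    if config.synthetic is not None:
        syn = dict(config.synthetic)
        expr_params = syn.pop("expression", {})
        cat_params = syn.pop("complexes", {})
        syn.setdefault("seed", config.seed)
        collection, truth = generate_collection(**syn)
        specific_name = config.specific_network or collection.names[0]
        catalog = None
        if cat_params is not None:
            cat_params.setdefault("seed", _stage_seed(config, "gen-complexes"))
            catalog, collection, cat_truth = generate_complex_catalog(
                collection, specific_name, **cat_params
            )
            truth.modules = cat_truth.modules
            truth.specific[specific_name] = (
                truth.specific[specific_name] | cat_truth.specific[specific_name]
            )
        # expression rows for the collection's TFs; HK-involved TFs planted
        # as the stable group
        hk_tfs = {n for e in truth.backbone for n in e}
        if expr_params is not None:
            expr_params.setdefault("seed", _stage_seed(config, "gen-expression"))
            # every synthetic TF touches the backbone, so pad the matrix
            # with background genes standing in for TFs outside the HK set
            union = collection.union_nodes()
            background = [f"BG{i:04d}" for i in range(1, len(union) + 1)]
            expr_params.setdefault("genes", union + background)
            expr_params.setdefault("stable_genes", hk_tfs)
            expression, expr_truth = generate_expression(**expr_params)
            truth.stable_genes = expr_truth.stable_genes
            truth.variable_genes = expr_truth.variable_genes
        else:
            expression = None
        marker = truth.marker_set
        return collection, [], marker, catalog, expression, specific_name, truth

    collection = read_collection(config.manifest)
    gene_sets = [read_gene_set(p, name=name) for name, p in config.gene_sets.items()]
    marker = read_gene_set(config.marker_set) if config.marker_set else None
    catalog = read_complexes(config.complexes) if config.complexes else None
    expression = read_expression(config.expression) if config.expression else None
    specific_name = config.specific_network or collection.names[0]
    return collection, gene_sets, marker, catalog, expression, specific_name, None


def run_pipeline(config: RunConfig) -> dict[str, list[Path]]:
    """Execute the configured stages in order; returns the written files
    per stage."""
    outputs: dict[str, list[Path]] = {}
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    stage = "load"
    try:
        (collection, gene_sets, marker, catalog, expression,
         specific_name, truth) = _load_inputs(config)
        logger.info(
            "loaded %d networks (%d union TFs)",
            len(collection), len(collection.union_nodes()),
        )
        if config.synthetic is not None:
            input_dir = outdir / "inputs"
            manifest = write_collection(collection, input_dir)
            files = [manifest]
            if truth is not None:
                write_truth(truth, input_dir / "truth.yaml")
                files.append(input_dir / "truth.yaml")
            if marker is not None:
                write_gene_set(marker, input_dir / "markers.txt")
            if catalog is not None:
                write_complexes(catalog, input_dir / "complexes.tsv")
            if expression is not None:
                write_expression(expression, input_dir / "expression.tsv")
            outputs["load"] = files

        decomps = None

        def decompositions():
            nonlocal decomps
            if decomps is None:
                decomps = {net.name: vertex_sort(net) for net in collection}
            return decomps

        if config.stage_enabled("hierarchy"):
            stage = "hierarchy"
            layer_rows, summary_rows = [], []
            for net in collection:
                d = decompositions()[net.name]
                for node in sorted(net.nodes):
                    lo, hi = d.level_span[node]
                    layer_rows.append((net.name, node, d.layer[node], d.scc_id[node], lo, hi))
                props = layer_proportions(d)
                dist = link_distribution(net, d).fractions
                grc = global_reaching_centrality(net)
                summary_rows.append(
                    (net.name, props["top"], props["core"], props["bottom"],
                     props["isolated"], grc, *(dist[c] for c in sorted(dist)))
                )
                logger.info("%s: layers %.2f/%.2f/%.2f GRC=%.3f", net.name,
                            props["top"], props["core"], props["bottom"], grc)
            layer_df = pd.DataFrame(
                layer_rows,
                columns=["network", "node", "layer", "scc_id", "level_low", "level_high"],
            )
            dist0 = link_distribution(
                collection.networks[0], decompositions()[collection.names[0]]
            ).fractions
            summary_df = pd.DataFrame(
                summary_rows,
                columns=["network", "top_frac", "core_frac", "bottom_frac",
                         "isolated_frac", "grc", *sorted(dist0)],
            )
            outputs["hierarchy"] = [
                _write_tsv(layer_df, outdir / "layers.tsv", config),
                _write_tsv(summary_df, outdir / "hierarchy_summary.tsv", config),
            ]

        hk_edge_set = None
        if config.stage_enabled("conservation") or config.stage_enabled("entropy") \
                or config.stage_enabled("modules"):
            table = build_conservation(collection)
            hk_edge_set = housekeeping_edges(table)

        if config.stage_enabled("conservation"):
            stage = "conservation"
            files = [_write_tsv(table.to_frame(), outdir / "conservation.tsv", config)]
            hk_df = pd.DataFrame(sorted(hk_edge_set), columns=["regulator", "target"])
            files.append(_write_tsv(hk_df, outdir / "hk_edges.tsv", config))
            spec_rows = [
                (name, len(specific_edges(table, name))) for name in collection.names
            ]
            files.append(_write_tsv(
                pd.DataFrame(spec_rows, columns=["network", "n_specific"]),
                outdir / "specific_counts.tsv", config,
            ))
            curve = leave_k_out_curve(
                collection,
                k_max=config.param("k_max", min(5, len(collection) - 1)),
                n_subsets=config.param("n_subsets", 200),
                seed=_stage_seed(config, "leave_k_out"),
            )
            files.append(_write_tsv(curve, outdir / "leave_k_out.tsv", config))
            logger.info("HK edges: %d", len(hk_edge_set))
            outputs["conservation"] = files

        if config.stage_enabled("classify"):
            stage = "classify"
            reference = (
                Partition.from_labels(dict(collection.class_label))
                if config.synthetic is not None
                else reference_partition(collection)
            )
            k = config.param("k", reference.k)
            n_comp = config.param("n_components", 7)
            files = []
            summary = []
            for source in ("markers", "nnd"):
                if source == "markers":
                    if marker is None:
                        continue
                    features = target_feature_matrix(collection, marker)
                else:
                    features = nnd_feature_matrix(collection)
                points = pca_project(features, n_components=n_comp)
                part, Z = ward_cluster(points, k=k)
                from .classify import rand_index

                ri = rand_index(part, reference)
                labels_df = pd.DataFrame(
                    sorted(part.labels.items()), columns=["network", "cluster"]
                )
                files.append(_write_tsv(labels_df, outdir / f"clusters_{source}.tsv", config))
                newick = linkage_to_newick(Z, list(points.index))
                nwk_path = outdir / f"dendrogram_{source}.nwk"
                nwk_path.write_text(newick + "\n", encoding="utf-8")
                files.append(nwk_path)
                summary.append((source, ri))
                logger.info("classification (%s): RI=%.3f", source, ri)
            sweep = random_tf_set_sweep(
                collection,
                set_size=config.param("sweep_set_size", 5),
                n_draws=config.param("sweep_draws", 20),
                seed=_stage_seed(config, "sweep"),
                reference=reference,
                n_components=n_comp,
                k=k,
            )
            files.append(_write_tsv(sweep, outdir / "random_sweep.tsv", config))
            summary.append(("random_sweep_mean", sweep["rand_index"].mean()))
            files.append(_write_tsv(
                pd.DataFrame(summary, columns=["features", "rand_index"]),
                outdir / "classification_summary.tsv", config,
            ))
            outputs["classify"] = files

        if config.stage_enabled("enrich"):
            stage = "enrich"
            enrich_sets = list(gene_sets)
            if marker is not None:
                enrich_sets.append(marker)
            table_df = layer_enrichment_table(
                collection,
                decompositions(),
                enrich_sets,
                hub_fraction=config.param("hub_fraction", 0.2),
                alpha=config.param("alpha", 0.05),
            )
            outputs["enrich"] = [
                _write_tsv(table_df, outdir / "layer_enrichment.tsv", config)
            ]

        if config.stage_enabled("entropy") and expression is not None:
            stage = "entropy"
            hk_tfs = {n for e in hk_edge_set for n in e}
            if hk_tfs & set(expression.genes):
                ent_table, p = entropy_comparison(
                    expression, GeneSet(name="hk_involved", members=frozenset(hk_tfs))
                )
                files = [_write_tsv(ent_table, outdir / "entropy.tsv", config)]
                files.append(_write_tsv(
                    pd.DataFrame([("hk_vs_other_one_sided", p)], columns=["test", "p_value"]),
                    outdir / "entropy_test.tsv", config,
                ))
                logger.info("entropy comparison p=%.3g", p)
                outputs["entropy"] = files
            else:
                logger.warning("no HK-involved TFs among expression genes; entropy skipped")

        if config.stage_enabled("modules") and catalog is not None:
            stage = "modules"
            files = []
            try:
                spec_net = specific_subnetwork(collection, specific_name)
            except ValueError as exc:
                logger.warning("module detection skipped: %s", exc)
                spec_net = None
            if spec_net is not None:
                modules = complex_target_modules(
                    spec_net, catalog,
                    min_regulators=config.param("min_regulators", 2),
                )
                files.append(_write_tsv(
                    modules_to_frame(modules), outdir / "modules.tsv", config
                ))
                logger.info("complex-target modules: %d", len(modules))
            hk_net = DirectedNetwork.from_edges("hk", hk_edge_set) if hk_edge_set else None
            if hk_net is not None:
                dense = hk_dense_complexes(
                    hk_net, catalog,
                    min_members=config.param("min_members", 3),
                    min_density=config.param("min_density", 0.5),
                )
                files.append(_write_tsv(dense, outdir / "hk_dense_complexes.tsv", config))
            outputs["modules"] = files
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    return outputs
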