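#!/usr/bin/env python
"""Generate the synthetic study collection used by all downstream analyses.

Emulates, at desk scale, a collection of per-cell-type TF regulatory
networks: 150 TFs, 16 networks in eight classes (one singleton class playing
the role of the embryonic-stem-cell network), planted 23/67/10 layer
fractions, a shared housekeeping backbone, per-network specific edges,
class-structured marker wiring, a TF x tissue expression matrix whose
stable genes are the backbone-involved TFs, and a protein-complex catalog
with ten planted complex-target modules wired into the singleton network.

Writes everything (plus the planted truth) under results/synthetic/.
"""

from pathlib import Path

import yaml

from tfhier.network_io import write_collection, write_complexes, write_expression, write_gene_set
from tfhier.synthetic_data import (
    generate_collection,
    generate_complex_catalog,
    generate_expression,
    write_truth,
)

SEED = 14
OUT = Path(__file__).resolve().parent.parent / "results" / "synthetic"

CLASS_SIZES = {
    "blood": 3, "cancer": 1, "endothelia": 2, "epithelia": 2,
    "ESC": 1, "fetal": 1, "stroma": 4, "viscera": 2,
}


def add_hk_wired_complex(catalog, collection, truth):
    """Append one complex (HC9999) whose three members lie consecutively on
    the housekeeping backbone, so it is densely HK-wired by construction.

    Members are screened against shared ESC01-specific targets so the
    planted module census is unaffected.
    """
    from tfhier.conservation import build_conservation, specific_edges
    from tfhier.network_io import ComplexCatalog

    spec = specific_edges(build_conservation(collection), "ESC01")
    spec_targets: dict[str, set[str]] = {}
    for u, v in spec:
        spec_targets.setdefault(u, set()).add(v)
    succ: dict[str, list[str]] = {}
    for u, v in sorted(truth.backbone):
        succ.setdefault(u, []).append(v)
    for u in sorted(succ):
        for v in succ[u]:
            for w in succ.get(v, []):
                trio = (u, v, w)
                if len(set(trio)) < 3:
                    continue
                clean = all(
                    not (spec_targets.get(a, set()) & spec_targets.get(b, set()))
                    for i, a in enumerate(trio) for b in trio[i + 1:]
                )
                if clean:
                    return ComplexCatalog(
                        complexes={**dict(catalog.complexes), "HC9999": frozenset(trio)}
                    )
    raise RuntimeError("no clean backbone path of length 2 found")


def main() -> None:
    collection, truth = generate_collection(
        n_tfs=150,
        n_networks=16,
        class_sizes=CLASS_SIZES,
        layer_fractions=(0.23, 0.67, 0.10),
        core_extra_edge_prob=0.05,
        n_specific_per_network=60,
        marker_set_size=7,
        n_class_targets=8,
        n_class_edges=40,
        seed=SEED,
    )
    catalog, collection, module_truth = generate_complex_catalog(
        collection, "ESC01", n_complexes=20, n_planted_modules=10,
        targets_per_module=3, seed=SEED + 1,
    )
    truth.modules = module_truth.modules
    truth.specific["ESC01"] = truth.specific["ESC01"] | module_truth.specific["ESC01"]
    catalog = add_hk_wired_complex(catalog, collection, truth)
    hk_tfs = sorted({n for e in truth.backbone for n in e})
    background = [f"BG{i:04d}" for i in range(1, 151)]
    expression, expr_truth = generate_expression(
        n_tissues=79, noise_sd=0.05, concentration=0.05,
        genes=collection.union_nodes() + background,
        stable_genes=set(hk_tfs), seed=SEED + 2,
    )
    truth.stable_genes = expr_truth.stable_genes
    truth.variable_genes = expr_truth.variable_genes

    manifest = write_collection(collection, OUT)
    write_complexes(catalog, OUT / "complexes.tsv")
    write_expression(expression, OUT / "expression.tsv")
    write_gene_set(truth.marker_set, OUT / "markers.txt")
    write_truth(truth, OUT / "truth.yaml")
    with (OUT / "meta.yaml").open("w") as fh:
        yaml.safe_dump({"seed": SEED, "specific_network": "ESC01"}, fh)

    n_edges = [net.n_edges for net in collection]
    print(f"wrote {len(collection)} networks to {manifest.parent}")
    print(f"edges per network: min {min(n_edges)}, max {max(n_edges)}")
    print(f"planted backbone: {len(truth.backbone)} edges; "
          f"marker set: {sorted(truth.marker_set.members)}")
    print(f"planted modules in ESC01: {len(truth.modules)}")


if __name__ == "__main__":
    main()
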