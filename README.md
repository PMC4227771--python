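# tfhier

Hierarchy, conservation and wiring-based classification of human cell-type
transcription-factor (TF) regulatory networks.

A cell type can be described by a directed network whose nodes are TFs and
whose edge u → v means TF u binds the promoter of the gene encoding TF v.
Given a *collection* of such networks — one per cell type, sharing a common
TF vocabulary — this package answers the questions a systems biologist asks
of it:

* **Hierarchy.** Each network is vertex-sorted: strongly connected
  components are collapsed into a condensation DAG, leaf removal on the DAG
  and its transpose assigns level spans, and every TF lands in a top, core
  or bottom layer (top TFs regulate without being regulated, bottom TFs are
  only regulated, the core — including all non-trivial SCCs — does both).
  Steepness is quantified by reaching centralities: LRC(v) is the fraction
  of other TFs reachable from v, and GRC = Σ_v (C_max − LRC(v))/(N − 1).
* **Conservation.** An interaction present in every network is a
  housekeeping (HK) interaction; one present in exactly one network is
  specific to that cell type, and the subnetwork induced by a cell type's
  specific interactions is its specific network. A leave-k-out curve checks
  that the HK set is stable against dropping networks.
* **Classification.** Cell types are clustered from wiring features —
  binary indicators of which TFs are targeted by a small TF set A, or
  normalized node-degree (NND) profiles — via PCA (7 components), Ward
  clustering on Euclidean distances, and scored against a reference
  partition with the Rand index RI ∈ [0, 1].
* **Statistics.** Hubs (top 20% by out-degree, ties included) are tested
  for enrichment/depletion per layer with one-tailed hypergeometric tests;
  expression stability across T tissues is the relative entropy
  log2 T + Σ_j f_j log2 f_j of a gene's tissue profile; group comparisons
  use Wilcoxon rank-sum tests.
* **Modules.** For a protein-complex catalog, regulatory complex-target
  modules are maximal bicliques (R, B): two or more complex members R all
  regulating every TF of B through cell-type-specific interactions only.
  Complexes densely wired by HK edges are detected separately.

A seed-deterministic synthetic generator (`tfhier.synthetic_data`) builds
network collections with planted layers, backbone, specific edges, class
wiring, expression matrices and complex modules, so every stage is testable
end-to-end with exact expected answers. See `docs/methods.md` for the
models, parameter defaults and design decisions.

## Worked example

The `analysis/` scripts run the full study on a synthetic collection that
mirrors a 41-cell-type human study at desk scale: 150 TFs, 16 networks in
eight classes (one singleton class standing in for embryonic stem cells),
planted 23/67/10 layer fractions, a shared backbone, per-network specific
edges and ten planted complex-target modules.

```sh
python analysis/01_simulate.py
python analysis/02_hierarchy.py
python analysis/03_conservation.py
python analysis/04_classify.py
python analysis/05_enrichment.py
python analysis/06_modules.py
```

Output (abridged):

```
planted layers recovered exactly in 16/16 networks
mean layer fractions (top/core/bottom): 0.23/0.67/0.10
mean within-core link fraction: 0.89
GRC range: 0.083 - 0.083
LRC layer-ordering violations across all networks: 0

housekeeping interactions: 643 (equals planted backbone: True)
specific interactions per network: median 60, max 211 in ESC01
  (the designated stem-cell-like network: True)

marker-target features (7 TFs): RI = 1.000
NND profile features: RI = 1.000
random 5-TF sets: mean RI = 0.926 (sd 0.054)
label-permuted baseline: mean RI = 0.818; one-sided Wilcoxon p = 4.34e-08

core layer hub-enriched in 100% of networks (max hypergeometric p = 1.3e-06)
top layer hub-depleted in 100% of networks
median expression entropy: HK-involved 0.002 bits vs other 3.374 bits
one-sided Wilcoxon (HK stabler): p = 5.40e-51

ESC01-specific network: 122 TFs, 211 interactions, 33 hubs (total degree)
complex-target modules detected: 10 (planted: 10; exact recovery: True)
  example: complex HC1000, regulators TF0057+TF0146 -> targets TF0024, TF0128, TF0131
```

Reading the numbers: the vertex sort returns the planted three-layer split
in every network and the LRC ordering top > core > bottom holds without
exception; the HK intersection is exactly the planted backbone and the
singleton ESC-like class accumulates the most specific interactions (its
class wiring occurs nowhere else); the wiring of seven marker TFs separates
the eight classes perfectly (RI = 1), arbitrary 5-TF sets still classify
far above a label-permuted baseline; the dense core is hub-enriched in all
networks; TF genes on HK interactions are expressed far more stably; and
module detection returns the ten planted (R, B) bicliques with no false
positives. Tables land under `results/`.

The same analyses are available as a CLI over a YAML config
(`tfhier all --config run.yaml --seed 5 --outdir out/`), with subcommands
`simulate`, `hierarchy`, `conserve`, `classify`, `enrich`, `entropy`,
`modules`; every output carries a provenance header and fixed-seed runs
are byte-identical.

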