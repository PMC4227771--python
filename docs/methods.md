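# Methods

`tfhier` analyses collections of directed transcription-factor (TF)
regulatory networks — one network per cell type, nodes are TFs, an edge
u → v means TF u regulates the gene encoding TF v — and asks four kinds of
questions: how each network is organised vertically (hierarchy), which
interactions are shared or private across cell types (conservation), whether
wiring distinguishes cell types (classification), and which statistical
patterns (hub placement, expression stability, complex-level co-regulation)
follow from the first three. This note records the models, the parameters
that matter, and the design decisions taken where the procedures were
genuinely under-determined.

## Hierarchy: vertex sorting

Strongly connected components (SCCs) are collapsed into supernodes, forming
a condensation DAG D. Leaf removal on D (repeatedly deleting out-degree-0
supernodes) assigns every supernode the round index at which it disappears;
the same procedure on the transposed DAG gives a second index s, and with H
total rounds the node's level span is [low, H − s + 1], counting level 1 at
the bottom. Layers are then assigned at the condensation level:

* every member of a non-trivial SCC (size ≥ 2) is **core**;
* a singleton supernode with in-degree 0 and out-degree ≥ 1 in D is **top**,
  with out-degree 0 and in-degree ≥ 1 **bottom**, with both ≥ 1 **core**,
  and with neither **isolated**.

Design decisions:

* **Self-loops are removed** before SCC, leaf-removal and reachability
  computation: a single autoregulating TF is not a hierarchy. They are kept
  for degree statistics (hubs), where an autoregulatory edge counts once
  toward out-degree and once toward in-degree.
* **Isolated nodes** (no non-self edges) get an explicit fourth layer and
  are excluded from the top/core/bottom denominators, whose fractions
  therefore sum to 1 over hierarchically placed TFs. The isolated fraction
  is reported separately.
* The exact cut for singleton supernodes pinned between SCCs is fixed by the
  degree rules above; this is the documented contract, verified against an
  independent reachability-condensation oracle on 500 random digraphs.

Local reaching centrality (LRC) of a node is the fraction of the other
N − 1 nodes it reaches by directed paths; global reaching centrality is
GRC = Σ_v (C_max − LRC(v)) / (N − 1) with C_max the maximum LRC. GRC is 1
for a directed star and 0 for the complete symmetric digraph (both covered
by closed-form tests). LRC/GRC are computed on the condensation so one
reachability query serves an entire SCC; summation runs in sorted node
order so results are bit-reproducible.

## Conservation: housekeeping and specific interactions

Given a collection, each edge's occurrence count is the number of member
networks containing it (exact ordered symbol pairs; self-loops participate
like any edge). Housekeeping (HK) edges have count = n; specific edges have
count = 1 and belong to exactly one network. The specific subnetwork of a
member is the graph induced by its specific edges.

The leave-k-out curve reports, for k = 0..k_max, the size of the edge
intersection over the retained networks. All C(n, k) left-out subsets are
enumerated when they number at most `n_subsets` (default 200); otherwise
that many distinct subsets are sampled without replacement from a seeded
generator, so the curve is bit-reproducible. Defaults k_max = 5,
n_subsets = 200 keep the cost bounded; per-edge network membership is held
as bitmasks, so each subset costs one mask test per union edge.

## Classification from wiring

Two feature families describe each network over the **union** TF set of the
collection (a per-network feature length would make the vectors
incomparable; union with zero fill is the only workable reading):

* **target indicators** for a TF set A: entry (c, t) = 1 iff network c
  contains an edge a → t with a ∈ A;
* **NND profiles**: (in + out degree) / (2 × edge count), so each row sums
  to 1 by the handshake identity.

Rows are mean-centered (not scaled — the features are binary or already
normalised) and projected onto the first 7 principal components (capped at
rows − 1), each component's sign fixed so its largest-magnitude loading is
positive. Ward minimum-variance agglomeration on Euclidean distances — the
Ward.D2 convention, scipy's `linkage(method="ward")` — is cut at k clusters.
Partitions are scored with the Rand index, the fraction of item pairs on
which two partitions agree; the implementation uses contingency-table
combinatorics and is checked against pair enumeration.

The reference partition for real collections merges class labels into four
categories (stroma+epithelia; blood; endothelia; cancer+ESC+fetal); labels
not named by the merge map (e.g. viscera) keep their own category, since
the four-category convention does not place them. For synthetic collections
the planted class labels are the reference.

`random_tf_set_sweep` draws TF sets uniformly from the union regulator set
and reports the Rand index per draw; significance is assessed with a
one-sided Wilcoxon rank-sum test against the same sweep scored on a
label-permuted reference.

## Enrichment, entropy and rank tests

**Hubs** are the top `fraction` (default 0.2) of TFs by out-degree —
total degree for induced specific subnetworks, where direction alone is a
poor prominence measure — with all nodes tied at the rank-⌈0.2N⌉ degree
included. Tie inclusion means hub counts can slightly exceed 20%.

**Layer enrichment** uses one-tailed hypergeometric tests (enrichment
p = P[X ≥ x], depletion p = P[X ≤ x]) with the network's own TF set as the
universe (layer membership is per-network); the class set is intersected
with the universe first. Both tails are reported with a +/− call at a
configurable α (default 0.05) on the smaller tail; raw p-values are
reported, with multiple-testing correction left to the caller.

**Expression entropy** of a gene's tissue profile is
log2(T) + Σ_j f_j log2(f_j), f_j = e_j / Σ_k e_k, with 0·log2 0 ≡ 0 —
0 bits for perfectly uniform expression, log2(T) for single-tissue
expression. It is computed as Σ f_j log2(e_j T / Σ e_k), algebraically
identical but exactly 0 on constant rows. All-zero rows are flagged
degenerate at load time and excluded. The HK-stability comparison is a
one-sided Wilcoxon rank-sum test (HK-involved TF genes stabler, i.e.
smaller entropy).

**Wilcoxon rank-sum** uses exact null enumeration when n + m ≤ 12 with no
ties, otherwise the normal approximation with midranks, tie correction and
continuity correction (scipy's Mann–Whitney machinery; cross-checked
against full split enumeration).

An `empirical_rank_pvalue` helper provides the one-sided within-collection
rank test used to ask whether one network's layer size is an outlier; an
empirical null over the collection is the only null the data support.

## Complex-target modules

For a protein complex C and the specific-interaction network of one cell
type, a module is a pair (R, B): R ⊆ C with |R| ≥ 2 whose members all
regulate every TF in B through specific edges. A module is reported as a
**maximal biclique** under concept closure — B is the exact common-target
set of R and R is every present member covering B — because without
maximality each regulator sub-pair would count separately and the module
census would be ill-defined. Closure is computed per complex by
intersection saturation of the members' target sets; a `mode="all"` option
reports every (R, B) pair instead. Targets may themselves be complex
members. Enumeration is verified against subset brute force for complexes
with ≤ 15 present members.

A complex is **HK-dense** when, among its m ≥ 3 members present in the HK
network, the density of internal HK edges (ordered pairs, self-loops
excluded, denominator m(m−1)) reaches `min_density` and the internal HK
subgraph is weakly connected. "Highly connected" is not an established
quantity, so `min_density` (default 0.5) is a required, logged parameter.

## Synthetic data: what it emulates and what it does not

`generate_collection` builds n_networks networks over one TF set with:

* planted layers at the requested fractions (default 0.23/0.67/0.10): the
  core is made strongly connected **constructively** by a random
  Hamiltonian cycle (rejection sampling would not guarantee the planted
  decomposition at low density), top nodes only emit, bottom nodes only
  receive;
* a housekeeping backbone injected into every network: the cycle, one
  attachment edge per top/bottom node, dense-core extras drawn with
  `core_extra_edge_prob`, topped up to `n_backbone` random admissible pairs
  when that total is requested;
* per-network specific edges drawn from pools disjoint between networks and
  from the backbone, so the planted HK and specific sets are exactly what
  the conservation stage must return;
* class structure: a marker TF set A (default 7, the size of a small
  signalling family) wired to per-class target sets (default 8 targets,
  `class_target_overlap` of them shared across classes — 0 gives perfectly
  separable classes), plus `n_class_edges` shared per-class edges so that
  arbitrary TF draws also carry class signal. Specific pools exclude pairs
  whose source is a marker, so marker wiring is purely class-determined.

Bookkeeping corner cases are folded into the truth rather than ignored: a
singleton class's marker/class edges occur in exactly one network and are
recorded as specific; shared marker targets under overlap > 0 occur in
every network and are recorded as backbone.

Defaults mirror the geometry of a 41-cell-type human study (475 TFs, ~11k
edges per network, eight classes with one singleton); tests and the
analysis scripts scale the same construction down (60–150 TFs, 6–16
networks) so the whole pipeline runs in seconds.

`generate_expression` plants stable genes (one level with multiplicative
log-normal noise, `noise_sd`, exactly constant at 0) and tissue-restricted
genes (symmetric Dirichlet weights with small `concentration`; the
underflow limit degenerates to exact one-hot rows). `generate_complex_catalog`
injects R × B edges for each planted module into one designated network
only — guaranteeing specificity — and screens complex membership against
accidental co-targeting so the planted module census is exact.

What the generator does **not** emulate: footprint-level noise and motif
false positives, degree heterogeneity within layers (all core TFs are
statistically exchangeable), correlated edge loss between related cell
types, and any coupling between a TF's network role and its expression
level beyond the planted stable/variable split. Passing recovery tests
therefore demonstrates correctness of the calculus on networks with the
assumed structure, not robustness to the error modes of footprint-derived
data.

## Pipeline

`run_pipeline` executes load/generate → hierarchy → conservation →
classification → enrichment → entropy → module detection. Per-stage
randomness is derived by hashing (seed, stage name), so disabling one stage
never shifts another's stream, and stage toggles only select which outputs
exist. Every TSV carries a provenance header (version, seed, config hash);
two runs with the same config and seed produce byte-identical output trees.
In synthetic mode the expression matrix covers the collection's TFs plus an
equal number of background genes (every synthetic TF touches the backbone,
so a comparison group must come from outside it), with the HK-involved TFs
planted as the stable group.

## Known limitations

* The module census convention (maximal bicliques, one module per complex)
  is one of several defensible readings; `mode="all"` exposes the
  alternative.
* Ward tie-breaking follows scipy's cluster-index order; exact ties are
  measure-zero for continuous features but conceivable for binary features
  at tiny n.
* The hypergeometric layer tests treat layers as fixed samples; they do not
  model the dependence between layer assignment and degree, which is the
  point of the hub-enrichment observation rather than a nuisance.
* `leave_k_out_curve` means are exact only when subsets are enumerated;
  sampled means can dip non-monotonically within sampling error.
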