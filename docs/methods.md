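# Methods

## Scope and model

`netpharm` implements a network-pharmacology screening procedure in
which the targets of a multi-herb formula and the genes of a disease
are reconciled through their shared protein–protein interaction (PPI)
neighborhood.  The package deliberately consumes files (compound
tables, target mappings, edge lists, expression matrices, GMT
collections) rather than querying the live databases such analyses are
usually built on; database retrieval, identifier mapping, and network
visualization are out of scope.

## Compound screening

Compounds pass when OB ≥ 30 (percent) and DL ≥ 0.18, both comparisons
inclusive, matching the conventional "≥" phrasing of ADME screens.
Compounds kept on external pharmacological evidence despite
sub-threshold scores are expressed as a whitelist file rather than
hard-coded exceptions; the packaged reference table for the nine-herb
Yiqi Shexue formula ships with its 25-entry whitelist (8
literature-supported compounds and 17 amino acids of donkey-hide
gelatin, which all fail DL).  Duplicate records across herbs collapse
to one record whose herb set is the union of sources; the first-seen
scores win and conflicts are logged.  Per-herb tallies count each
compound–target pair once under every herb listing that compound, so
the per-herb sum can exceed the number of distinct pairs; both numbers
are reported.

## Differential expression

The disease gene list comes from a small two-group comparison of
log2-scale intensities.  No test is canonical for this step in the
legacy microarray setting; the package uses the two-sided Welch
unequal-variance t-test with Welch–Satterthwaite degrees of freedom,
the textbook choice for tiny two-group designs, implemented over
`scipy.stats.ttest_ind(equal_var=False)`.  A gene is called when
*p* < 0.005 and |log2FC| > 1, both strict, with **no**
multiple-testing correction — the screen intentionally mirrors the
raw-threshold convention, and the thresholds are config knobs.
Zero-variance degeneracies are defined rather than propagated as NaN:
if both groups are constant, *p* = 1 for equal means and *p* = 0
otherwise.  Inputs are assumed log2-transformed; a reader flag applies
log2(x + 1) to linear-scale data.  No normalization, batch correction
or probe collapsing is attempted.

## Networks and the two-stage screen

Seed sets are expanded to their one-hop neighborhood in the background
interactome: the induced subgraph on the seeds present in the
interactome plus all their direct neighbors (expansion depth is a
config knob; neighbor–neighbor edges are included because the subgraph
is induced).  The two expanded networks merge by **node intersection**
with the union of edges between retained nodes — intersection (not
union) semantics are what make the merged network smaller than either
input and focused on the shared neighborhood.

The screen then proceeds in two stages, all comparisons strict:

1. nodes with degree > 2 × (median degree of the merged network);
2. on the stage-1 induced subnetwork, nodes strictly above the
   subnetwork medians of all six centralities simultaneously.

Centralities and their medians are recomputed on the subnetwork, not
inherited from the merged network.  Medians of even-length samples are
the mean of the two middle order statistics.

### Centrality definitions and numerics

* **DC** — degree.
* **BC** — betweenness, unnormalized, summed over unordered pairs
  (Brandes' accumulation; unreachable pairs contribute zero).
  Unnormalized values are used because the screen's published
  thresholds are on that scale.
* **CC** — closeness with a reachable-count numerator,
  r_v / Σ d(v,u), which handles disconnected graphs without
  infinities; isolated nodes score 0.
* **EC** — principal adjacency eigenvector, non-negative, unit
  Euclidean norm.  Power iteration runs on (A + I): the shift leaves
  eigenvectors unchanged but guarantees a strictly dominant eigenvalue,
  without which the iteration oscillates on bipartite graphs.
  Convergence is a max-norm change < 1e-10 (default) within 10,000
  iterations; failure raises with the residual.  On disconnected
  graphs the mass concentrates on the dominant component and a warning
  is emitted.
* **LAC** — mean degree of v's neighbors within the subgraph induced
  by N(v); 0 for isolated nodes.
* **NC** — Σ over incident edges of ECC(v,u) = z / min(deg v − 1,
  deg u − 1), z = common-neighbor count; a zero denominator
  contributes 0.

## Enrichment and the core gene

Over-representation uses the exact upper-tail hypergeometric
probability P(X ≥ k), evaluated by integer combinatorial summation
(`math.comb` and an exact rational, converted to float once), so it is
correct to the last digit at any size used here.  The conservative
EASE convention (test k − 1 instead of k) is an optional flag.  The
universe defaults to all genes annotated in the collection and is
overridable.  FDR control is Benjamini–Hochberg (via statsmodels),
applied across the terms that overlap the query; only such terms are
reported.  Significant terms and their overlapping genes form a
bipartite gene–pathway network; genes are ranked by unnormalized
betweenness on that network, ties broken lexicographically, and the
top gene is reported as the core target gene.  Gene-set collections
are flat (no GO DAG topology).

## Synthetic data and what it does (not) show

The generator supplies every input with the minimal structure the
screen assumes:

* **Interactome**: preferential attachment (Barabási–Albert, n = 1000,
  m = 3 by default) — connected, simple, heavy-tailed.  The default
  bundle augments it with a *rich club*: the 30 highest-degree nodes
  are additionally wired pairwise with probability 0.5.  Real curated
  interactomes show exactly this dense hub core, and without it the
  clustering-sensitive measures (LAC, NC) of hubs are noise — a
  six-measure consensus screen then has no coherent truth to recover.
* **Compound library**: 60 compounds over 9 herbs, 70% forced to pass
  OB/DL (scores uniform on [0,100] × [0,1], rejection-sampled to the
  wanted side; 1–3 source herbs each).
* **Compound targets**: 90% of passing compounds receive 3–18 targets
  drawn degree²-weighted from the non-hub tier plus 2–5 "famous"
  rich-club targets, emulating the hub bias of curated drug-target
  space.
* **Expression**: 1000 genes (95% on the interactome), 5 samples per
  group, baseline uniform on [4,12] log2 units, iid Gaussian noise
  σ = 0.3; 200 planted genes shifted by 3 log2 units (half up, half
  down), drawn from non-hub interactome genes on the chip.  Five
  samples per group are used because a Welch test at n = 2 per group
  (the smallest conceivable two-group design) cannot reach
  p < 0.005 at this effect size — its degrees of freedom are ~2.
* **Gene sets**: 40 terms of 10–40 genes; 3 planted terms draw ~70%
  (≥ 60%) of members from the planted hub set, the rest uniform.

The planted hub truth is the top decile of interactome degree
intersected with the pooled candidate genes (compound targets plus
planted differential genes) — by construction essentially the rich
club.  Over seeds 0–9 the full pipeline recovers the planted hubs with
~0.95 precision and ~0.95 recall, recovers ≥ 90% of planted
differential genes, and finds all three planted terms at FDR < 0.05.

Passing these tests shows the machinery is internally coherent: the
statistics are computed correctly and the screen finds the structure
it presupposes when that structure is present.  It does **not** show
that real formula-disease analyses are robust — real interactomes
carry study bias, expression series have batch structure and probe
effects, and annotation databases are incomplete in correlated ways,
none of which the generator emulates.

## Determinism and problem sizes

All generators derive from a single integer master seed
(`numpy.random.default_rng`), and every writer sorts its output, so a
fixed seed reproduces every artifact byte for byte.  Default problem
sizes (1000-node interactome, 1000-gene chip, 40 terms) were chosen so
a full pipeline run takes about a second and the complete test suite a
few minutes on one CPU while still exhibiting the heavy-tailed regime
the screen targets.

## Known limitations

* One-hop induced-subgraph expansion is the only implemented semantics
  (depth is configurable; non-induced variants are not).
* The merge assumes both inputs are induced subgraphs of one
  interactome; merging networks from different backgrounds is
  unsupported.
* No weighted or directed networks; no approximate betweenness for
  very large graphs.
* Alternative hub-selection schemes (k-core, MCC) are not implemented.
* The DE module is a thresholded Welch test, not a moderated-variance
  model; with very few samples per group its power is limited by
  design.
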