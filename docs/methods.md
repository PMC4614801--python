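# Methods

`modcross` implements a functional-module view of the molecular link between
two disease conditions — here labelled *inflammation* and *cancer* — from
three data layers: multi-dataset gene expression, a scored protein–protein
interaction (PPI) network, and curated TF/miRNA→target regulation tables.
This note records the models, the defaults and why they are set where they
are, the numerical choices, and what the synthetic test bed does and does
not establish.

## Differential expression

Per dataset, each gene g is scored with the SAM-style relative difference

    d_g = (x̄_disease − x̄_normal) / (s_g + s0)

where `s_g` is the pooled standard error of the mean difference and `s0` a
non-negative stabiliser that keeps low-variance genes from dominating the
ranking. By default `s0` is the **median of the gene-wise pooled standard
errors**; the original SAM procedure instead searches percentiles of the
`s_g` distribution to minimise the coefficient of variation of `d`. The
median is a transparent one-line stabiliser with very similar behaviour on
log-scale expression, and `s0` is exposed as a parameter for anyone who
wants a stricter variant.

Significance uses group-label permutations: all distinct label assignments
are enumerated when there are no more of them than `n_permutations`
(default 100), otherwise that many random assignments are drawn from a
seeded generator. For a symmetric cutoff t on |d| the estimated FDR is

    FDR(t) = median_perm #{|d_perm| ≥ t} / #{|d_obs| ≥ t}

and the calling threshold is the smallest t with FDR(t) ≤ the target
(default 0.01). Gene-wise q-values are the FDR at the gene's own |d|, made
monotone non-decreasing toward weaker genes and capped at 1. When no cutoff
reaches the target the dataset contributes no calls (logged, not an error).

Integration across a context's datasets applies two rules: a gene must be
called in **at least two** datasets, and **every** call must agree in
direction. A direct disease-vs-disease contrast (both "groups" are disease
states) runs through the same machinery; when only a single such comparison
exists, `min_datasets=1` makes that single table the support.

Degenerate inputs: a gene with zero within-group variance and `s0 = 0`
raises by default (`on_zero_variance="error"`); the `"inf"` option flags it
with ±∞ instead. Groups need ≥ 2 samples each, otherwise the pooled
variance is undefined and construction fails.

## Interactome handling

Interaction tables are 3-column (geneA, geneB, score). Scores are
confidences on [0, 1]; tables printed on the 0–999 integer scale are
detected (any score > 1) and divided by 1000. The high-confidence filter
keeps scores **≥ 0.9 inclusive** — "cutoff of 0.9" is read as retaining
boundary scores, and the choice is stated here because edge counts depend
on it. Duplicate pairs collapse to the maximum score; self-loops are
dropped with a logged count. Gene identifiers are opaque case-sensitive
symbols; alias resolution is upstream curation and out of scope.

Integrated DEGs are mapped as the induced subgraph, and each context keeps
its maximal connected component (MCC). Ties on component size are broken by
the component containing the lexicographically smallest gene id, so runs
are reproducible.

## Module detection (MCODE)

Vertex weighting is the core-clustering coefficient: for vertex v, take the
subgraph induced by v and its neighbours, find its highest k-core, and set
weight(v) = k × density(core), density = 2E/(n(n−1)). Complexes are then
seeded from the highest-weight unvisited vertex (ties: lexicographic id)
and grown breadth-first to `max_depth`, admitting a neighbour whose weight
strictly exceeds (1 − node_score_cutoff) × seed weight. Weights are
computed once on the input graph, not recomputed during growth, and every
vertex reached during growth is marked visited whether or not its complex
survives post-processing — complexes never overlap. Post-processing:
haircut (default on) iteratively removes members with fewer than two
in-complex neighbours (the complex 2-core); fluff (default off) adds
outside neighbours whose closed neighbourhood density exceeds
`fluff_density_cutoff`; complexes without a non-empty `k_core_min`-core
(default 2) are discarded. Module score is density × size, and modules are
reported in score order. Defaults (node_score_cutoff 0.2, k-core 2, haircut
on, fluff off, depth 100) are the algorithm's published defaults. No
module-size floor is imposed beyond the k-core rule; 3-gene triangles are
legitimate modules.

A documented behaviour, inherent to the admission rule: two equally dense
modules joined by even one bridge edge merge into a single complex, because
members of either side pass the other's weight threshold. Modules whose
core weights differ by more than the admission factor (e.g. cliques of
distinct sizes) separate cleanly. The planted-module recovery study
therefore uses weight-separated plantings; mergers of equal-weight adjacent
modules are the algorithm's correct output, not a detection failure.

## Crosstalk significance

For an inflammation module A and cancer module B, crosstalk edges are the
network edges joining A\B to B\A. Edges touching shared genes (A ∩ B) are
deliberately excluded and reported separately as *common* genes/edges:
shared structure and crosstalk are different readouts, and counting both
would double-count the intersection's internal wiring. The
`include-shared-endpoint-edges` convention is therefore "exclude", fixed
and documented.

The null model preserves every node's degree exactly: double edge swaps
with uniformly chosen edge pairs and random orientation, rejecting
proposals that would create a self-loop or parallel edge, until
`swaps_per_edge × |E|` successful swaps (default 10×|E|). On rigid graphs
(a triangle; a 3-path) where few or no swaps are possible, the proposal
budget (200× the target) runs out and the current, still degree-identical
graph is returned with a log message. One ensemble of `n_random` networks
(default 1000) is generated per run and shared by all module pairs.

The empirical p-value follows the strict-inequality counting rule

    p = (1/N) Σ_i S_i,  S_i = 1 iff null count_i > observed,

flagged significant at p < 0.05, with no multiple-testing correction across
pairs — both exactly as the method prescribes. A conservative variant,
(#{null ≥ obs} + 1)/(N + 1), and BH across pairs are available behind flags
(default off). Two calibration facts, both measured by the test suite:

* With modules that are random gene sets (exchangeable under the null),
  the rejection fraction at α = 0.05 sits inside the 99% binomial band
  around 0.05 at 210 pairs, N = 200.
* With *planted-dense* modules the test is strongly conservative: the real
  network sequesters member edges inside modules, while randomization
  frees them, so null inter-counts exceed observed ones and p stacks near
  1. This is a property of the published test itself, worth knowing when
  interpreting non-significant pairs between dense modules.

## Pivot regulators

A regulator (TF or miRNA — identical logic, different label) is a pivot for
a significant pair when, in **each** module: it has **more than 2** targets
(strict, i.e. ≥ 3; a `min_targets` switch allows ≥ 2), and its targets are
enriched with upper-tail hypergeometric p < 0.05. The background universe
is the node set of the filtered interactome — modules live in that graph;
the genome would dilute and the MCC would over-restrict — and it is a
parameter. Target sets are intersected with the background before drawing
counts. No correction across regulators is applied by default, matching
the plain per-module 0.05 rule; BH is available behind a flag.

## Enrichment

Generic gene-set over-representation: per term, upper-tail hypergeometric
p on the background-restricted sets; BH step-up across the terms of one
query; significant at q < 0.05. BH is applied per queried module, not
pooled across modules, matching per-module function labels. Zero-overlap
terms are reported with p = 1 rather than skipped so the BH denominator is
identical across queries.

## Synthetic study design

The generator emulates the study's three layers with enumerable truth:

* **Interactome** — Barabási–Albert background (attachment m = 2 per new
  node) for a right-skewed degree distribution, so degree-preserving
  randomization is a non-trivial null. Planted modules overlay extra edges
  (never removing any): a random spanning tree for connectivity, then
  random internal edges up to ⌈density × C(size, 2)⌉, so planted density is
  a lower bound. Planted crosstalk fixes the **total** inter-edge count
  between a pair's exclusive members (background crossings count toward the
  quota; if they already exceed it, generation fails loudly rather than
  deleting edges). All edges carry score 1.0.
* **Expression** — per context, independent Gaussian datasets
  (noise_sd = 1, log-scale, null mean 0). True DEGs are the context's
  planted module members plus a uniform 30% of the remaining genes, each
  with one direction, shifted by effect × noise (default 5σ) in the disease
  group of every dataset of that context. The 30% background fraction
  exists because mapping only ~50 module genes onto a 1000-gene network
  shatters into per-module components and the MCC step would discard all
  modules but one; with it, the mapped subgraph has a giant component the
  way a real DEG set (thousands of genes) does.
* **Regulators** — planted pivots get `targets_per_module` (default 4)
  targets inside each of their two modules, padded with uniform targets to
  the decoy target count (20); decoys draw 20 targets uniformly.

Default study: 1000 genes, five modules per context (sizes 8–12, density
0.9), two crosstalk pairs with 12 planted inter-edges, one pivot TF and one
pivot miRNA, three datasets per context, 10 samples per group. All
generation flows from one seed through named per-stage streams, so
identical configs give byte-identical outputs.

What the synthetic bed does **not** emulate: probe/batch effects and
normalization artefacts, gene-length or GC biases, correlated expression
within modules, evidence-channel structure in interaction scores, or
regulator activity. Passing tests therefore demonstrate the statistical
machinery (calibration, power at the planted effect sizes, exact counting,
reproducibility) — not performance on real microarray data.

## Problem sizes in the checks

The automated checks run at desk scale chosen to keep the full suite in a
few minutes: 1000-gene networks (~2000–3700 edges), permutation ensembles
of 200 (1000 for the end-to-end run in the acceptance script), 100
label permutations per DEG call, and 10–25 generator seeds per study.
These sizes are stated here so the measured rates are read against the
conditions that produced them.

## Known limitations

* The double-edge-swap chain is run for a fixed 10×|E| successful swaps,
  a standard mixing heuristic, not a proven mixing time.
* MCODE merging of equal-weight adjacent modules (above) bounds what
  planted-recovery can promise on crowded networks.
* The DEG permutation FDR uses the median permuted exceedance count; SAM's
  90th-percentile s0 search and asymmetric cutoffs are not implemented.
* The crosstalk test's conservatism for dense module pairs means real
  crosstalk between tightly-wired modules needs a larger edge excess to
  reach significance.
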