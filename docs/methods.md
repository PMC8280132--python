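# Methods

This note documents the models, statistics and design choices behind
`mbnet`, and what its synthetic benchmark does and does not establish.

## Seed mapping

A biomarker metabolite contributes proteins through two routes:

* **Pairwise associations** (HMDB-style table): exact name match after
  case-folding and whitespace trimming; no synonym resolution is
  attempted (curated inputs are expected to use consistent names).
* **Metabolic-map enzymes**: "path length" counts compound-to-compound
  hops on an undirected compound graph whose edges carry enzyme
  labels. An enzyme is *within path length L* of a metabolite when it
  labels an edge whose nearer endpoint is at hop distance ≤ L−1. With
  the default L = 2 this includes every enzyme acting on the
  metabolite itself or on any of its direct reaction partners — the
  reading that reproduces the packaged L-glutamate worked example
  (twelve first- and second-shell enzymes in, carbamoyl-phosphate
  synthase out). Traversal is undirected; reaction directionality is
  not modelled.

A metabolite present in both sources contributes the union. Per-disease
seed sets are unions over that disease's biomarkers; a biomarker
labelled for both diseases contributes to both.

## Disease network

Edges survive from the scored interactome when both endpoints are seed
proteins (any score) or exactly one endpoint is a seed and the score
strictly exceeds 0.7. Consequences worth knowing:

* nodes exist only through retained edges — seed proteins with no
  surviving interaction are absent;
* every non-seed node is adjacent to a seed node (pendant or hub-star
  structure in sparse regions);
* per-disease edge counts are computed by re-applying the rules to one
  disease's seed set alone (one of several possible readings; reported,
  never asserted against external numbers).

Topology statistics follow common network-viewer conventions: the mean
local clustering counts degree-0/1 nodes as zero; characteristic path
length and diameter are computed on the largest connected component;
the power-law statement is descriptive (least-squares slope of
log count vs log degree), not a formal fit.

## DPClusO-style clustering

No reference pseudocode exists for the overlapping variant, so the
implementation follows the DPClus lineage with the overlap mechanism
made explicit:

* edge weight = number of common neighbours; node weight = sum of
  incident edge weights (computed once, on the full graph);
* growth from a seed node admits, each round, the first candidate (by
  connections-to-cluster desc, node weight desc, id asc) that keeps the
  induced density ≥ d_in and has cluster property
  E_nk/(d_k·|N_k|) ≥ cp_in (default 0.5, the value used throughout the
  DPClus literature); a single-node cluster has density 1 by
  convention;
* the outer loop seeds only *uncovered* nodes (max weight, then degree,
  then id) but grows on the full graph, which is what produces
  overlaps, and marks grown nodes covered — each round covers at least
  one new node, so termination and full coverage are guaranteed.

Density and cluster-property thresholds are compared in exact rational
arithmetic (thresholds converted via `Fraction(...).limit_denominator`),
so admissions are free of floating-point edge cases and the clustering
is provably invariant to edge-file row order.

Two bookkeeping notes. Coverage forces singleton clusters; summaries
therefore report both all-cluster and size-≥2 statistics, and
singletons are excluded from enrichment (`min_report_size = 2`). At
d_in = 1.0 every multi-node cluster is a clique, and since each
coverage round yields one cluster there can be at most n clusters —
fewer than the number of maximal cliques a graph may contain — so the
procedure enumerates *a* clique cover, not all maximal cliques.

## Enrichment statistics

* One-sided Fisher exact test: P(X ≥ k) for the hypergeometric
  distribution with population N, K annotated, n drawn (enrichment
  direction only, the DAVID convention).
* EASE score: the same tail with the overlap discounted by one
  (`max(k−1, 0)`), so single-gene overlaps can never be significant.
* Bonferroni (`min(1, p·m)`) and Benjamini–Hochberg step-up, applied
  per family: all size-≥2 clusters of one density run for disease
  enrichment; all pathways tested for one cluster for pathway
  enrichment. Selection uses BH FDR (< 0.05 for clusters, ≤ 0.05 for
  pathways); Bonferroni is reported but plays no selection role.
* Pathway filters follow annotation-tool defaults: count ≥ 2,
  EASE ≤ 0.1, FDR ≤ 0.05. The pathway background is the union of all
  pathway genes and network nodes (configurable).
* In the pipeline, clusters are scored for enrichment of the
  biomarker-derived disease proteins S (SCZ and BD pooled;
  `per_disease` switches to separate sets). The reference disease-gene
  list is reserved for ROC truth. The `score_clusters` operation is
  agnostic and works with any disease set.

## Prioritization

SScore(protein) = −log₁₀(FDR) of the smallest-FDR size-≥2 cluster
containing it; FDR is floored at 1e−16 before the logarithm (log base
only rescales scores and cannot change rank-based results). Proteins
covered only by singletons score 0. ROC truth labels are
reference ∪ seed-set, restricted to network nodes; negatives are the
remaining network nodes (an explicit choice — proteins outside the
network are not counted as missed positives, and the excluded count is
visible in the run report). The ROC groups tied scores, so AUC equals
the tie-corrected Mann–Whitney statistic; density selection takes the
maximal AUC with ties resolved toward the smaller density.

## Synthetic world

The generator emulates the six inputs with planted structure, in the
sparse-interactome regime where this analysis operates (mean network
degree ≈ 4–5):

| ingredient | default | why |
| --- | --- | --- |
| protein universe | 800 | large enough to hold modules + distractors |
| modules | 5, 48–60 nodes, overlap 3 | protein functional modules; consecutive-module overlap gives overlapping-cluster ground truth |
| within-module edge prob. p_in | 0.13 | realized induced density ≈ 0.13, i.e. nearest the sweep's lowest density 0.1 — sparse modules, as in real PPI networks |
| background edge prob. p_out | 0.002 | sparse noise; must satisfy p_in ≫ p_out |
| edge scores | Beta(8,2) within, Beta(2,8) background | the >0.7 rule passes ~80% of true edges and ~0.04% of noise |
| disease modules | 4 of 5 | reference genes concentrate in most (not all) biomarker modules; the fifth module is a null control for reference-based tests |
| disease odds / background rate | 10 / 0.10 | odds ratio of reference-gene membership inside disease modules |
| distractor hubs | 40 seeds × 6 disjoint partners, scores 0.7+0.3·Beta(2,2) | curated hub complexes: biomarker-associated proteins outside any module whose high-confidence partners are the network's non-seed (negative-class) nodes |
| pathways | 12, alignment 0.5, 8 noise genes | half the gene sets are planted module supersets (disease modules first), half random |
| metabolites | 10 | each tied to one module: 60% of the module via associations, 40% via map-fragment enzymes within path length 2, plus a decoy enzyme at distance 3 that mapping must *not* pick up |

Every generator is a pure function of (config, seed); identical inputs
reproduce byte-identical files. Protein ids are zero-padded so
lexicographic tie-breaks are deterministic.

**What the demo world establishes, and what it does not.** Module
recovery, significance, pathway ranking and determinism are exercised
end to end against known ground truth. Two deliberate simplifications
matter for interpretation. First, distractor neighbourhoods are
*exchangeable* (equal size, uniformly high scores, disjoint), so every
distractor cluster carries an identical enrichment record; as a result
the per-density AUC in the demo pipeline ties exactly across the sweep
and the selection rule's tie-break (toward the smaller density) picks
0.1, the density matching the planted modules' internal density. The
genuinely discriminating behaviour of the AUC — the matched density
beating a grossly mismatched one — is asserted separately with
reference-gene-scored clusters, where fragmentation at high density
destroys statistical power (prioritization test suite). Second, real
interactomes have heavy-tailed degrees, inter-module bridges and
annotation noise that the generator does not model; a green synthetic
suite validates the machinery, not biological conclusions.

## Numerical and degenerate-input conventions

* scores outside [0, 1], malformed rows, self-loop compounds and
  unknown disease labels raise parse errors with line numbers;
  duplicate interactions keep the maximum score; self-interactions are
  dropped.
* empty biomarker lists, empty networks, empty pathway collections and
  ROC labelings with a single class raise explicit errors; an empty
  *result* (no enriched pathway) is a valid outcome.
* all tabular outputs are comment-headed TSV written with a fixed float
  format, making reruns byte-comparable; `report.json` additionally
  carries timestamps and is excluded from byte-level comparisons.

## Known limitations

* No synonym/ID normalization for metabolites or proteins; inputs must
  use consistent identifiers.
* Metabolic maps are undirected; reaction direction and currency
  metabolites are not modelled.
* The per-disease interaction counts depend on an interpretation of
  "common interactions" that the available description leaves open.
* DPClusO here is a faithful re-derivation from the published lineage,
  not a port of the original binary; identical cluster lists with other
  implementations are not guaranteed (the coverage, density and
  connectivity invariants are).
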