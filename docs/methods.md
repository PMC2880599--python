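# Methods

## Model

`toposig` treats a curated protein-interaction network as a directed graph
over normalized entity identifiers, with typed edges (transcriptional
regulation, binding, phosphorylation, other), signed effects (activation /
inhibition / unspecified) and a small integer trust weight. The scoring
model makes three structural assumptions:

1. **Influence follows directed reachability.** A regulator can affect any
   node reachable downstream of it, regardless of edge type or sign; the
   *dependency graph* of a regulator is its full downstream closure.
   Effects and trust are carried through ingest and IO but are deliberately
   ignored by the traversal: dependency is traced for activating and
   inhibiting chains alike, and trust-weighted or pathway-aware proximity
   variants are out of scope.
2. **Proximity is unweighted step count.** `d(R, n)` is the length of the
   shortest directed path; unreachable means infinitely far. When a
   competing regulator C is at least as close to a target as R is
   (`d(C, n) <= d(R, n)`, ties excluded on purpose), that target is not
   specific to R and is removed from R's set before enrichment.
3. **Enrichment is sampling without replacement.** Under the null, a
   regulator's target set is an arbitrary draw from the measured universe,
   so the DE count in it follows a hypergeometric law; we use the exact
   upper tail (no normal approximation; verified against big-integer
   enumeration to 1e-12).

Per dataset, every node with out-degree >= 1 is scored: the full target set
and each competitor-excluded reduction are tested and the smallest p-value
is kept ("best score"), with the chosen competitor recorded.
Benjamini–Hochberg q-values are assigned across all scored regulators of
that dataset; gene-level and protein-level DE sets are always scored
separately, never pooled. Ordering is ascending p with ties broken by
larger DE-target count, then identifier; `percentile = 100·(1 −
(rank − 0.5)/m)` over the m scored records (rank 1 of 577 prints as 99.9).

## Parameters

| parameter | default | meaning |
|---|---|---|
| `min_de_targets` | 2 | below this DE-member count in every variant a regulator is reported *un-scored* (`too_few_de_targets`) rather than given a meaningless p |
| `min_set_size` | 3 | variants smaller than this are not eligible for best-score selection |
| `max_depth` | unlimited | cap on downstream path length (dependency graphs are full closures by default) |
| `max_candidates` | 50 | competitive regulators examined per regulator, ranked by shared-target count (ties lexicographic) |
| `de_side` | `up` | which DE flag counts as success; the main analyses use up-regulated lists |
| `fdr_q` | 0.05 | significance threshold on BH q-values |
| ratio thresholds | 1.2 / 0.83 | iTRAQ-style up/down cut-offs, boundaries inclusive, configurable |

Identifier normalization is uppercase + whitespace strip only; no probe or
accession mapping is attempted — inputs are assumed to carry pre-mapped
symbols. Duplicate (source, target, type) edges collapse to the maximum
trust; self-loops are dropped at ingest (a node must not be its own
target). The reference universe for topological scoring is the measured
universe of the DE set being scored, so enrichment is computed over
assayable entities only; the reference for functional gene-set enrichment
of regulator lists is the whole network node set.

## Synthetic data

The generator emulates a two-platform signaling study: a layered network
(20 receptors → 50 kinases → 100 TFs → 1000 target genes by default, one
backbone parent per node plus Poisson(2) cross edges per signaling node;
TF→target edges are transcriptional regulation, upstream edges are
binding/phosphorylation/other). A handful of *cascade heads* (receptors or
kinases, 5 by default) are planted active: each target downstream of a
planted head is up-regulated with probability 0.8 (`activation_prob`),
undriven targets are flagged with probability 0.02 in either direction
(`background_de_prob`). The transcript view reports flags directly
(microarray-style FDR-selected lists); the protein view detects each
transcript-level change with probability 0.2 (`protein_detection_prob`),
adds its own background noise, and expresses flags as treated/control
ratios drawn so the 1.2/0.83 thresholds recover them exactly (up ~
U(1.2, 3.0), down ~ U(0.4, 0.83), unchanged ~ U(0.84, 1.19)). At these
defaults the two up-lists overlap weakly (mean Jaccard ≈ 0.19 over 50
seeds), emulating the poor cross-platform concordance of paired designs.
One functional "process set" per planted cascade (the head plus its full
downstream closure) serves as ground truth for enrichment analyses.
Everything is deterministic given the seed.

What the generator does **not** model: measurement error in ratios beyond
thresholding, correlated noise between platforms, differing measured
universes per platform (both views share the target layer), feedback loops
(the layered graph is acyclic up to cross edges within layers' order), hub
structure of real interactomes, and any identifier-mapping ambiguity.
Passing tests therefore demonstrate algorithmic correctness and behaviour
under the simulated regime, not performance on real interactome-scale data.

Fixed fixtures: the worked single-cascade example (receptor→kinase→TF with
36 targets, 10 over-expressed, embedded among 264 unchanged background
genes so that target-set enrichment is computed against a realistic
measured universe — with only the cascade in the universe, significance
would be arithmetically impossible); its competitive-regulation extension
(a second, non-DE target block closer to a competing kinase); an
AR-style truncation scenario (a TF with 45 direct DE targets plus an
independent three-node growth-factor cascade); and a synthetic stand-in
for published up/down gene/protein lists that reproduces their set
arithmetic (347/70 sharing 13; 257/39 sharing 3) with synthetic
identifiers.

## Numerical choices

- Distances come from one multi-source unweighted Dijkstra sweep
  (scipy.sparse.csgraph) over the simple directed view; competitor
  exclusions are boolean mask operations on the distance matrix, and the
  hypergeometric tails for all variants of a regulator are evaluated in one
  vectorised call. A separate, plain per-node BFS implementation of the
  same operations exists in `dependency_attribution` and the two routes are
  asserted equal in tests.
- Ties in best-score selection prefer the full (unexcluded) target set,
  then competitors in their deterministic candidate order.
- Degenerate inputs: empty DE sets yield all-unscored output (reason
  codes `no_targets`, `too_few_de_targets`, `too_few_targets`), not errors;
  empty universes are errors; `percent_of_smaller` is reported as missing
  when either set is empty.
- All randomness flows through explicit integer seeds (numpy Generator);
  iteration is always over sorted containers so runs are byte-reproducible
  across processes.

## Design choices where the design was open

- **Enrichment statistic:** one-sided hypergeometric upper tail — the
  standard choice for gene-set over-representation and exactly testable.
- **Multiple testing:** BH across all scored regulators per dataset.
- **Percentile convention:** midpoint formula above, chosen to reproduce
  conventional "top 0.1%" readings at m in the hundreds.
- **Truncation** removes direct transcriptional DE targets from the DE
  lists only; network and universe are untouched, so re-scored enrichment
  is computed against the same background.
- **Random-extension control** enriches the *extended DE list itself*
  against the functional collection. Routing the control through the
  scoring stage instead couples the query size to the padding level and, at
  desk scale, can make fully-contained sets look *more* significant as the
  significant list contracts to the cascade core; the direct route measures
  dilution cleanly.

## Known limitations

- **Best-score selection is anti-conservative.** Taking the minimum
  p-value over up to `max_candidates` competitor-excluded variants is a
  selection step that the reported p-value does not adjust for. On
  complete-null simulations the full-set p-values control the BH false
  discovery rate at the nominal level, but best-score selection inflates
  the realized false-discovery proportion at q = 0.05 by roughly a factor
  of 2–3 (about 0.13 observed over 200 null replicates). Interpret the
  q-values as a ranking device, not an exact error-rate guarantee, or set
  `max_candidates` low when calibrated error control matters.
- The two-platform views share one measured universe and the protein view
  is a thinning of the transcript view, so their DE lists are nested rather
  than complementary; cross-platform convergence of inferred regulators
  shows up robustly in mean overlap but not uniformly in every replicate.
- Unweighted step distance ignores edge trust and sign; a kinase two
  trusted steps away and a speculative binding chain of length two are
  treated identically.
- Hub nodes with very large dependency graphs can score well on bulk
  reachability; the competitor-exclusion step mitigates but does not
  eliminate this.
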