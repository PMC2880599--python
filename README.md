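# toposig

Upstream-regulator inference on directed protein-interaction networks by
**topological significance scoring**, with paired-platform (transcriptome +
proteome) analysis tools and a synthetic-data generator that makes the whole
pipeline testable end to end without any external downloads.

## The problem

High-throughput assays flag differentially expressed (DE) genes or proteins,
but the signaling proteins that *caused* those changes — receptors, kinases,
adapters — are usually regulated post-translationally and look unchanged in
the data. They stay hidden from a per-gene analysis. Worse, transcript-level
and protein-level DE lists from the same samples typically share only a small
fraction of members, so naive set comparison suggests the two platforms
disagree.

`toposig` addresses both problems by scoring each network node on the
behaviour of its *downstream targets* rather than on its own measurement.

## The method

For every regulator R (any node with outgoing edges) in a directed
interaction network:

1. **Dependency graph.** Trace all directed paths downstream of R; the
   measured nodes in this closure are R's *remote targets* `T(R)`, each with
   an unweighted shortest-path distance `d(R, t)`.
2. **Competitive exclusion.** For each competing regulator C that can also
   reach part of `T(R)`, drop the targets at least as close to C
   (`d(C, t) <= d(R, t)`), leaving the targets specific to R.
3. **Enrichment.** Score each target-set variant with the exact
   hypergeometric upper tail

   `P(X >= k) = Σ_{i>=k} C(K, i) C(N-K, n-i) / C(N, n)`

   where `N` is the measured universe, `K` the DE count, `n` the variant
   size and `k` its DE members. The *best* (smallest) p across variants
   characterises R.
4. **FDR and ranking.** Benjamini–Hochberg q-values across all scored
   regulators; regulators with `q <= 0.05` are *topologically significant*.
   Ranks and percentiles (`100·(1 − (rank − 0.5)/m)`) summarise the ordering.

Second-stage operations: direct-target **truncation** (remove a TF's direct
transcriptional DE targets and re-score, to delineate signaling that does not
depend on that TF), **concordance** reports between identifier sets,
functional **gene-set enrichment** (GMT collections) of significant-regulator
lists, and a **random-extension control** that pads DE lists with random
identifiers and verifies that enrichment significance decays.

## Worked example

The package ships a fixed fixture of the classic hidden-regulator situation:
a receptor (FGFR3) binds a kinase (P90RSK2) which phosphorylates a
transcription factor (ATF4) controlling 36 target genes, 10 of which are
over-expressed — while receptor and kinase themselves show no expression
change. The cascade is embedded among 264 unchanged background genes.

```python
import toposig as ts
from toposig import ReferenceUniverse

truth = ts.worked_cascade_fixture()
records = ts.score_all(truth.network, truth.gene_view,
                       ReferenceUniverse.of(truth.gene_view.universe))
for r in records:
    if not r.unscored:
        print(r.regulator, r.n_targets, r.n_de_targets,
              f"{r.p_value:.3e}", f"{r.q_value:.3e}", r.rank)
```

prints

```
P90RSK2 37 11 2.075e-11 4.380e-11 1
FGFR3   38 11 2.920e-11 4.380e-11 2
ATF4    36 10 1.662e-09 1.662e-09 3
```

All three cascade nodes are topologically significant (q far below 0.05)
although two of them are invisible in the expression data: 10 of the 36
remote targets are over-expressed where roughly one in thirty background
genes would be expected by chance. The kinase and receptor carry 37/38
targets because the measured universe includes the TF (itself over-expressed)
and the kinase.

## Command line

```bash
toposig simulate --out data --seed 7            # synthetic network + DE views
toposig score    --network data/network.tsv --de data/de_gene.tsv --out run
toposig full     --network data/network.tsv --de data/de_gene.tsv \
                 --de data/de_protein.tsv --gmt data/process_sets.gmt \
                 --out run --seed 7 --truncate-regulator R013
```

`full` runs score → truncate+rescore → concordance → functional enrichment →
random-extension control and writes TSVs, a `summary.txt` and a
`manifest.json` (config + input hashes + seed) that makes every run
reproducible byte for byte. Exit codes: 0 ok, 2 validation error, 3 stage
failure.

## Layout

- `toposig.network_model` — domain types, edge-list/SIF/DE-table/GMT IO,
  identifier normalization
- `toposig.dependency_attribution` — dependency graphs, remote targets,
  competitor exclusion, direct targets
- `toposig.topo_scoring` — enrichment p-values, best-score selection,
  BH-FDR, ranks/percentiles (vectorised engine)
- `toposig.downstream_analysis` — truncation, concordance, gene-set
  enrichment, random-extension control
- `toposig.synthetic_data` — simulation generator and fixed fixtures
- `toposig.cli_pipeline` — the `toposig` command

See `docs/methods.md` for modelling assumptions, parameter defaults and
known limitations.
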