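# ptmnet

**Post-translational modification (PTM) types in the context of protein
interaction network (PIN) topology.**

Proteins are regulated by covalent modifications — phosphorylation,
acetylation, ubiquitination, glycosylation and others — and by the
protein–protein interactions they engage in. `ptmnet` asks whether proteins
carrying a particular PTM type occupy characteristic positions in the
interaction network, and provides the complete statistical pipeline to
answer it: from raw multi-source PTM site records and edge lists to
fold-change matrices, co-existence networks, cross-protein PTM interaction
enrichment, GO-term enrichment and disease-association tests. A synthetic
generator with planted, individually recoverable effects stands in for
database downloads, so every stage is testable end to end.

The package is aimed at computational/systems biologists who want either
the individual statistical operations (as an importable library) or the
whole pipeline (as a `ptmnet` command).

## The statistics at the core

For a node $n$ of the high-confidence interaction graph (edge confidence
$\geq 0.9$, components $<100$ proteins pruned):

* degree $k_n$ — number of incident edges;
* clustering coefficient $C_n = 2e_n / (k_n(k_n-1))$, with $e_n$ the number
  of connected pairs among $n$'s neighbours; undefined for $k_n<2$ and then
  excluded from statistics;
* closeness centrality $C_c(n) = 1 / \sum_m L(n,m)$, the reciprocal summed
  shortest-path length to all other nodes of $n$'s component.

For each PTM type $T$ with carrier set $S_T$ (consolidated experimental
sites only; types with $>1000$ sites, species with $\geq 1000$ sites;
length- and site-count-outlier proteins removed), carriers are compared to
non-carriers per property with a two-sided Mann–Whitney test; effect size
is $\log_2(\mathrm{median}_{S_T} / \mathrm{median}_{\bar S_T})$; p-values
are Benjamini–Hochberg adjusted per property across species, PTM types and
network sources, and only groups with $\geq 30$ carriers are tested.

Same-protein co-existence of two types is scored by the Jaccard index
$|S_A \cap S_B| / |S_A \cup S_B|$ with a one-sided Fisher exact test;
cross-protein interaction preference crosses, over all unordered pairs of
one-PTM-type-only proteins, the pair's label combination against whether
the pair interacts (one-sided Fisher, FDR per species, types with $<10$
labeled proteins excluded). GO enrichment supports classic per-term Fisher
and the *elim* decorrelation (leaf-upward traversal; significant terms'
study genes are removed from their ancestors before those are tested).
Disease overlap tests whether the top/bottom degree, clustering or
closeness quartile of a PTM set is enriched for disease proteins.

## Worked example

`examples/03_compare_ptm_properties.py` plants a degree bias for
phosphorylation (carriage probability $\propto (k+1)^1$) and none for
acetylation on a 2000-protein scale-free network, then runs the comparison
machinery:

```
     acetylation     degree: log2 fold +0.000 (median), FDR p 5.39e-01, direction lower
     acetylation clustering: log2 fold +0.087 (mean), FDR p 9.02e-01, direction higher
     acetylation  closeness: log2 fold -0.005 (median), FDR p 8.43e-01, direction lower
 phosphorylation     degree: log2 fold +0.585 (median), FDR p 4.38e-23, direction higher
 phosphorylation clustering: log2 fold +0.121 (mean), FDR p 1.14e-12, direction higher
 phosphorylation  closeness: log2 fold +0.062 (median), FDR p 6.71e-14, direction higher
```

The planted type is recovered — phosphoproteins have ~1.5× the median
degree of non-carriers (log2 fold 0.585) at FDR p ≈ 1e-23 — while the
unbiased type shows near-zero folds and non-significant p-values.
`(mean)` marks cells where the median-based fold is degenerate (zero or
tied medians) and the mean-based fold is reported instead.

The other examples cover input simulation, network metrics, co-existence,
cross-protein crosstalk, and GO/disease enrichment; each prints a short
interpretation of its numbers.

## Command line

```sh
ptmnet simulate --outdir inputs --seed 1     # synthetic input bundle
ptmnet run --config pipeline.yaml            # full pipeline, stage TSVs + manifest
ptmnet metrics edges.tsv --out props.tsv     # single stages as subcommands
```

With no configured inputs, `ptmnet run` simulates its own and executes
every stage (consolidation → network → comparisons → co-existence →
crosstalk → GO → disease), writing one TSV per stage plus `manifest.json`
with the config echo, row counts and seed.

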