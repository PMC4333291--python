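# Methods

This note documents the models, parameter choices and numerical conventions
behind `ptmnet`, in the order the pipeline runs them.

## PTM record consolidation and filtering

A PTM record is one experimentally verified modification site:
(species, protein, 1-based sequence position, residue, PTM type, optional
subtype, source database). Computationally predicted records are rejected
at ingest. Records from different source databases describing the same
(species, protein, position, type) are consolidated into one record
carrying the union of source labels; sources occasionally disagree on the
residue at a site, in which case all claims are retained (first seen is
the representative) and a warning is emitted — position and type, not
residue, define a site.

Abundance filtering keeps PTM types with **strictly more than 1000** sites
globally, then species with **at least 1000** sites across the retained
types; the intersection is the working dataset. Retention is decided once,
on the consolidated set, and not recomputed after outlier removal (the
filters are described in that order and the alternative would couple the
thresholds to the outlier rule).

Outlier removal is per species (a flag switches to global): proteins whose
sequence length falls strictly below the 1st or strictly above the 99th
percentile of the observed length distribution are removed first
(percentiles by linear interpolation between order statistics, the common
"type 7" rule, so the boundary is well defined and testable); then
proteins whose total site count (distinct consolidated sites, all types
pooled) is ≥ mean + 3·sd are removed, with mean and sd computed after the
length removal. The sd is the sample standard deviation (ddof = 1). Two
degenerate cases are deliberate no-ops: species with fewer than three
proteins (percentiles/sd undefined) and zero-variance site counts (no
protein can then be an outlier, although every count "equals" mean + 3·0).

Protein sets per type come in three modes: `all` (a protein appears in
every type set it has a record for), `one-type-only` (proteins carrying
exactly one distinct type; sets are then pairwise disjoint — used to
remove co-occurrence confounding), and `subtype` (sets keyed by subtype,
e.g. S/T vs Y phosphorylation, N- vs O-linked glycosylation).

## Interaction networks and node properties

Edge lists are read in a STRING-like dialect (protein1, protein2,
combined_score; scores above 1 are interpreted as STRING's native 0–999
integers and divided by 1000) or a minimal MITAB dialect (first two
columns, "prefix:value" identifiers stripped at the first colon; a missing
score counts as 1.0 since curated binary interactions are experimentally
verified). Self-loops are dropped, duplicate and reversed edges merged
keeping the maximum confidence, and edges below the confidence threshold
(default 0.9) discarded. Connected components with fewer than 100 nodes
are pruned; on realistic inputs one giant component remains, which is
reported but not enforced.

The three metrics are unweighted. Clustering for degree < 2 is *undefined*
and excluded from all downstream statistics (a toggle provides the
0-convention for comparison with tools that use it). Closeness is the
**unnormalised** reciprocal distance sum over the node's own component;
a normalisation flag multiplies by (component size − 1) — the group
comparisons are invariant to that choice because it rescales both groups
equally. Batch computation uses scipy's C shortest-path kernel
(`csgraph.shortest_path`, unweighted) per component; the per-node
functions use plain BFS and agree to 1e-12 (asserted in tests).

## Group comparisons

Each PTM set is intersected with the network universe and compared to its
complement (proteins not carrying *this* type; they may carry others — a
mode switch provides the stricter no-PTM-at-all reference). The test is a
two-sided Mann–Whitney with normal approximation and tie correction (exact
enumeration is infeasible at the group sizes involved, and the degree and
clustering distributions are heavily tied). Groups with fewer than 30
members holding a valid value are flagged untested.

The effect size is log2(median carrier / median non-carrier). Two
degenerate cases fall back to the mean-based fold, flagged as
mean/median-discordant: a zero median (clustering medians are often 0),
and exactly tied medians — common on discrete degree distributions, where
a real shift can leave both group medians at, say, 4. Direction follows
the medians, falling back to the means only on an exact tie; the
discordance flag also marks cells where mean- and median-based folds
disagree in sign.

FDR is Benjamini–Hochberg with one family per network property, pooling
all species, PTM types and network sources (a `global` single-family mode
exists for sensitivity analysis). Untested cells render empty in the
fold-change matrix; significance marks are `*` (FDR < 0.05) and `**`
(FDR < 0.01), with `~` appended for discordant cells.

## Co-existence, crosstalk, GO and disease tests

All 2×2 tests share one code path: the one-sided enrichment p is the
hypergeometric upper tail, identical to Fisher's exact test with the
"greater" alternative (asserted exhaustively against tail sums for all
tables with universe ≤ 25 in the tests).

**Co-existence** (same protein, two types): Jaccard index plus the Fisher
test on [in A?] × [in B?]. The default universe is the species'
PTM-carrying proteome — the dataset's natural universe, available without
a proteome inventory; a full-proteome universe can be passed explicitly.
This is the key documented choice of the module: under the PTM-carrying
universe, independent type pairs sit at or slightly below chance
expectation (the universe is conditioned on carrying something), which
makes the one-sided enrichment test conservative, never anti-conservative.
An edge is significant when FDR < 0.01 (family: all pairs within one
species) *and* the observed overlap exceeds its independence expectation.

**Crosstalk** (interacting proteins, two types): proteins in the pruned
network carrying exactly one type are labeled; types with < 10 labeled
proteins are excluded. Over all unordered pairs of labeled proteins the
table crosses [label multiset = {a,b}] × [pair is an edge]. Non-edges are
counted within the labeled universe only (label-conditional test; a
whole-network universe would mix labeling and interaction effects).
Self-pairs (a,a) count pairs of two distinct type-a proteins. One-sided
enrichment by default, two-sided available. FDR per species across all
type pairs.

**GO enrichment**: annotations are closed over is_a ancestors before
testing (cycles are a hard error naming an offending edge). `classic`
tests every term; `elim` walks terms by increasing longest-path depth from
the leaves (ties broken by term id, making runs reproducible), and when a
term's raw p falls below alpha (default 0.01) its study∩term proteins are
removed from the gene lists of all strict ancestors before those are
tested. A fully eliminated term is still reported (p = 1) rather than
dropped. With alpha ≤ 0 no elimination fires and elim equals classic
term-for-term (asserted). FDR per namespace; the top-terms heatmap takes
each type's top five significant terms, cells −log10 FDR p (0 where not
significant), and orders rows and columns by average-linkage hierarchical
clustering with Euclidean distance, inputs pre-sorted by label so distance
ties resolve deterministically.

**Disease overlap**: within a PTM type's network proteins, the top (or
bottom) quartile of a property — quantiles computed within the focal PTM
set's own distribution by default; a global-quantile mode exists — is
tested for disease-protein enrichment over the network universe, one-sided
Fisher, one FDR family across all types × properties × tails.

## The synthetic generator

The generator emulates the study's inputs with known ground truth. Graph
models: preferential attachment (default, n = 2000, m = 3 — giving the
heavy-tailed degree distribution interaction networks show),
uniform-random, and stochastic block. Edge confidences are Uniform(0.9, 1)
so the default filter keeps everything. Default PTM types echo the
relative abundance of the major human types — phosphorylation (carriage
rate α 0.35, ~4 sites/carrier), acetylation and ubiquitination (0.20, ~3),
glycosylation (0.08, ~2) — with glycosylation deliberately below the
1000-site abundance threshold at the default network size, exercising the
filter the way low-frequency types were dropped in the original data. All
planted effects default to **off**.

Planted effects, each recoverable by exactly one downstream module:

* degree bias β: carriage probability ∝ (k+1)^β, scaled to the baseline
  rate and capped at 1. (k+1) rather than k keeps leaf nodes at nonzero
  probability.
* coupling ρ (same-protein co-existence): with probability ρ a protein's
  carriage of type t is copied from its carriage of type s — a simple
  mixture that is monotone in ρ and has the closed-form independence
  Jaccard αβ/(α+β−αβ) as its ρ=0 baseline.
* edge assortativity φ (crosstalk): a fraction φ of edges is replaced by
  edges between random s- and t-carriers. The degree sequence is *not*
  preserved; the graph stays simple (a failed rewire after 100 tries
  restores the original edge).
* disease bias γ: label probability ∝ rate·(k+1)^γ.
* GO skew: one leaf term's annotation rate is multiplied for carriers of a
  chosen type, on a balanced toy DAG (default depth 3, branching 3, leaf
  rate 0.05).

Sites are uniform positions without replacement on LogNormal lengths
(median ≈ 450 residues, σ = 0.5); residues come from per-type alphabets
(S/T/Y for phosphorylation, K for acetylation/ubiquitination, …) purely
for format realism. Multi-source duplication (default 2 sources, duplicate
rate 0.3) exercises consolidation. A seed fully determines every output
file, byte for byte.

What the generator does **not** emulate: degree–degree correlation
structure beyond the three models, realistic GO DAG shape, sequence-level
realism, cross-database identifier mess. Passing tests therefore show the
*statistics* behave correctly under known conditions, not that the
biological conclusions transfer to any particular database snapshot.

## Validation experiments and problem sizes

`ptmnet.experiments` packages the validation runs used by the test suite
and the reproducibility script. Null calibration uses 200 replicate label
draws (n = 2000 networks; n = 1000 with 3×50 labels for crosstalk) and
checks that significant fractions stay at or below nominal FDR levels.
Recovery experiments use 100 seeded replicates at the conditions each
effect targets: β = ±, 300 carriers, n = 2000; ρ = 0.5 between two
rate-0.15 types, n = 2000; φ = 0.3 with two 50-protein one-type-only sets,
n = 1000; γ = 2 at disease rate 0.1. These sizes keep each experiment in
the seconds-to-a-minute range on one CPU while leaving the power analyses
meaningful.

Measured at these conditions, the positive degree bias (β = 1), the
coupling, the assortativity and the disease bias are each recovered in
~100/100 replicates. The *negative* degree bias at β = −0.5 is recovered
in only ~75–85/100: on a preferential-attachment graph the minimum degree
equals m, most nodes sit at k = 3–6 where (k+1)^−0.5 barely varies, so the
planted downward shift is intrinsically small and the two-sided test at
p < 0.01 has limited power. This is a property of the generative model at
those parameters, reported as measured.

## Known limitations

* Identifier namespaces are assumed pre-mapped; the optional two-column
  mapping table is applied verbatim and unmapped records are dropped.
* Only is_a edges of the ontology are honoured; other relationship types
  are ignored with a warning.
* The Mann–Whitney normal approximation is inaccurate for groups barely
  above the 30-member threshold combined with extreme ties; p-values there
  should be read as approximate.
* Plots are deliberately out of scope; the TSV/JSON outputs are the
  contract.
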