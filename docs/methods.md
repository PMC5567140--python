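# Methods

This note documents the statistical models, the defaults and the design
choices behind `mirmint`, and what the synthetic benchmark does and does
not establish about real data.

## Differential expression

**Moderated t (mRNA arm).**  For each feature the two-group linear
model gives the log2 fold change (treated − control mean) and a pooled
variance *s²_g* with *d_g = n₁ + n₂ − 2* residual df (pooled, not
Welch, matching the linear-model convention of array analysis).  The
empirical-Bayes prior (*d₀*, *s₀²*) is fitted by moment-matching the
marginal distribution of *z = log s²_g* under the scaled-F hierarchical
model: with *e = z − ψ(d_g/2) + ln(d_g/2)*,

- Var *e* = ψ′(d_g/2) + ψ′(d₀/2), so ψ′(d₀/2) is the excess of the
  observed variance of *e* over ψ′(d_g/2), inverted by Newton
  iteration;
- *s₀² = exp(ē + ψ(d₀/2) − ln(d₀/2))* for finite *d₀*.

A non-positive excess means no detectable variance heterogeneity:
*d₀ = ∞* and *s₀²* is the arithmetic mean of the sample variances.  The
posterior variance is *s̃² = (d₀s₀² + d_g s²)/(d₀ + d_g)* and the
moderated t is referred to a t distribution on *d₀ + d_g* df, capped at
the pooled residual df across all features so the infinite-prior limit
still has a proper reference distribution.  The implementation was
checked against an independent re-derivation (root-finding instead of
Newton) in the test suite, and agrees with the R reference
implementation of the same hierarchical model to < 1e-13 in t and p on
both a homogeneous-variance and a heterogeneous-variance fixture.

Zero-variance features are floored at machine epsilon, flagged, and
excluded from the prior fit — this keeps their t finite while
preserving the ranking.  Missing values are rejected at load: a 3v3
design cannot tolerate silent imputation.  Features (probe sets) are
the unit of analysis; collapsing multiple probes to a gene symbol is
the caller's concern, and reproducing published probe-level counts
depends on that collapsing rule.

**Plain t (miRNA arm)** is the ordinary pooled two-sample Student t.
Both arms report BH-adjusted p-values, but by convention the mRNA
filter uses the adjusted column and the miRNA filter the raw column.
The fold-change filter operates on the signed linear scale:
|fc_signed| ≥ 1.5 ⇔ |log2FC| ≥ log2 1.5, with direction `up`/`down`
assigned only when the p-criterion (strictly below the threshold) is
also met.

**BH adjustment** delegates to `statsmodels` (`fdr_bh`), with input
validation and an exhaustive step-up oracle in the tests.

## Pre-ranked enrichment

The ranked list is sorted by signed fold change, descending, with ties
broken lexicographically on the feature id so results are
deterministic.  The enrichment score of a set is the extremum of
*P_hit(i) − P_miss(i)*, where *P_hit* accumulates |score|^p mass over
in-set items (normalised by the total in-set mass) and *P_miss* counts
out-of-set items (normalised by N − N_H).  Defaults: weight exponent
p = 1 (the conventional weighted statistic; p = 0 reduces exactly to
the classical two-sample KS statistic on ranks, verified against
`scipy.stats.ks_2samp`), set-size bounds 15–500 for pathway analysis.
If every in-set weight is zero (possible only with p > 0 and all-zero
scores) the weights fall back to uniform.

The permutation null shuffles tags: for each distinct set size, B
(default 1000, minimum 100) random same-size subsets of the ranked
items are scored, and the pool is shared by all sets of that size —
phenotype permutation is impossible for pre-ranked input and is not
offered.  NES = ES divided by the absolute mean of same-sign null ES
of the same size; the nominal p is the same-sign tail proportion, with
an exact zero reported as < 1/B and stored as 1/(B+1) so −log
transforms stay finite.  The FDR q is the GSEA-style ratio of the
pooled same-sign null-NES tail fraction to the observed-NES tail
fraction, clipped to [0, 1] and monotonised within each sign (each q
becomes the minimum over all less-extreme same-sign sets, the step-up
analogue).  Significance is the joint rule p < 0.05 and q ≤ 0.25; the
q boundary is inclusive and configurable.

## Consensus targets and integration

A (miRNA, gene) pair is kept when any source marks it experimentally
validated or when it appears in at least `hit_threshold` (default 5)
distinct databases; database names are compared case-insensitively
because aggregated resources capitalise inconsistently, while
miRNA/gene identifiers stay opaque case-sensitive strings (no
mature-arm normalisation — callers can pre-map identifiers).

Integration couples the filtered DE tables through the kept links.  The
default construction (`mirna_ranked`) ranks the DE miRNAs by signed
fold change and builds one set per DE mRNA (the DE miRNAs targeting
it); the per-up-gene and per-down-gene collections are run separately,
with distinct permutation seeds and FDR pools, and merged.  The
alternative reading (`mrna_ranked`) ranks the DE mRNAs and uses
per-miRNA target sets; here the full signed ranking is analysed in a
single run, because a regulon concentrated in one expression direction
is visible precisely as clustering at one end of the signed ranking —
splitting the universe by sign would make member ranks exchangeable
within each run and destroy the signal.  Both constructions are
first-class because the underlying flow admits either; the recorded
`direction` field keeps provenance.  Target sets use min_size 3 (miRNA
regulons are small; the pathway floor of 15 would discard nearly all),
a deliberate deviation from the pathway default.  No anti-correlation
filter is imposed: both sign combinations of regulator and target are
admissible.  Enriched miRNAs/targets are the leading-edge members and
set owners of sets passing the joint p/q rule, and every reported
association is backed by a kept consensus link.

## Annotation and network

A miRNA is annotated with a significant pathway when its enriched
targets intersect the DE genes belonging to that pathway; the overlap
genes are the evidence.  Category labels (Apoptosis, Proliferation,
Signaling, Chemotaxis, Cancer, Motility, Cholesterol, Migration,
Differentiation) come from an editable keyword map, because any such
grouping is curation, not computation.  The network is a typed directed
graph — miRNA →(targets)→ gene →(member_of)→ pathway — with signed
fold changes as edge weights: a targeting edge carries the
*regulator's* FC, a membership edge the *gene's* FC (the edge belongs
to the gene).  Signs are preserved rather than absolute-valued so
up/down edges remain distinguishable in a viewer.  Exports: SIF plus a
companion edge-attribute TSV, GraphML, and an edge TSV embedding node
attributes that re-imports to an isomorphic graph.  No layout,
rendering or topological statistics are computed.

## Synthetic-data generator

The generator emulates the study design: three samples per group, log2
expression with baseline ~ Normal(7, 2) (a plausible microarray
dynamic range), planted signed effects on a `frac_de` = 10% subset of
features with magnitudes ~ |Normal(1.5, 0.15)| split 50/50 up/down,
and residual Normal(0, 0.5) noise.  Defaults for the target compendium
are eight databases at per-database recall 0.7, a spurious-link rate
of 1e-4 per pair per database, and a 10% experimentally validated
subset emitted under a pseudo-source (`validated_experiment`) even
when no prediction database recalls the link.  Each miRNA receives 30
true targets; a DE miRNA draws 80% of them from planted DE genes of
the opposite sign — the repression structure that makes an
up-regulated miRNA's regulon detectable among down-regulated genes.
Gene sets: 50 sets with sizes uniform on [15, 50]; 20% of them draw
80% of their members from planted DE genes of a single sign
(alternating up/down), the rest uniformly.  miRNA matrices are emitted
already normalised — the miRNA platform's own normalisation is not
modelled.

A single integer seed drives one root `SeedSequence`; each artifact
(mRNA matrix, miRNA matrix, target links, gene sets) uses a fixed
spawned sub-stream, so adding a stage never perturbs earlier draws and
identical configurations produce byte-identical files.

**What passing tests show — and don't.**  The generator's noise is
i.i.d. Gaussian on the log scale with exchangeable spurious links; real
arrays have correlated probes, intensity-dependent variance, batch
structure, and target databases whose errors are anything but
exchangeable.  Recovery rates measured here therefore demonstrate the
*correctness* of the statistical machinery under its own model, not
expected operating points on real data.

## Numerical choices and problem sizes

Quantile normalisation resolves ties by assigning each tied group the
mean of the reference values at the ranks it occupies, which makes the
transform exactly idempotent; it is a no-op with a warning on a
single-sample matrix.  Trigamma inversion uses Newton iteration with
the standard 0.5 + 1/y start; permutation draws use
`numpy.random.Generator.choice` without replacement; ES extremum ties
between the positive and negative candidate resolve to the positive
one.  The test suite scales the multi-seed benchmarks to keep the
default run around fifteen seconds: 10 seeds with 200–250 permutations
and a few hundred features per run, with thresholds kept proportional
to the larger illustrative versions (e.g. recovery in ≥ 9 of 10
seeds).  The acceptance script runs the full pipeline at the
generator's defaults (2000 genes, 300 miRNAs, 1000 permutations) in a
few seconds.

## Known limitations

- Starts from probe-set summaries: no CEL parsing, background
  correction or probe summarisation, and no probe→gene collapsing.
- Two-group designs only; no covariates, pairing or array weights.
- The enrichment universe for pathway analysis is the filtered DE
  list ranked by fold change, matching the upstream flow; results are
  conditional on the DE filter.
- Gene-set and target databases are always local files; no live
  retrieval and no identifier aliasing.
- Whether an input matrix is already normalised cannot be
  auto-detected; the CLI takes explicit `--already-log` / `quantile`
  flags instead of guessing.
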