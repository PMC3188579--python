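# Methods

`seqtally` implements a complete bulk RNA-Seq differential-expression
pipeline: reference ingestion, read preprocessing, exhaustive short-read
alignment, rule-based gene counting, replicate quality assessment, an exact
negative-binomial test with mean-dependent dispersion, and GO-term
enrichment. This note records the models, the numerical choices, and the
limits of what the synthetic-fixture tests demonstrate.

## Reference catalog and splice junctions

The catalog is built from a FASTA reference and a GFF3 annotation
(`gffutils` resolves ID/Parent links; structurally malformed records and
unresolvable parents are collected as record-level rejects rather than
dropped). Internally all coordinates are 0-based half-open; GFF3 I/O
converts to and from the 1-based inclusive convention.

Because the aligner is ungapped, splice-junction sequences substitute for
spliced alignment: for every adjacent exon pair of every isoform, the last
`flank` nt of the upstream exon are joined to the first `flank` nt of the
downstream exon, in transcript orientation. With `flank = read_length - 1`
(default 24 for 25-nt reads) any read crossing the junction lies fully
within the junction sequence. Exons shorter than the flank contribute their
full length and the junction is flagged `short`. Identical junction
sequences within one gene are collapsed. Gene and transcript type
vocabularies are open sets read from the GFF3; unknown types are kept.

## Alignment

The index hashes every reference position by its leading *preamble* k-mer
(default 12 nt) into containers; within a container, entries are sorted by
a 64-bit integer packing the following 16 nt (2 bits per base: A=00, C=01,
G=10, T=11), so exact words are located by binary search and empty
containers are never stored. Positions are indexed wherever the full
preamble fits; within 16 nt of a sequence end the suffix key packs the
available bases left-aligned. Indexing only full 28-nt words would leave
tail placements of reads shorter than the word undiscoverable, so the
preamble is the indexing unit and the suffix is an acceleration structure.
Positions whose preamble contains a non-ACGT base are not indexed, and
candidate windows containing such bases never produce hits.

Each read is queried in both orientations with two equal-length seeds (the
first and second preamble-length windows). A placement with at most `k`
total mismatches leaves at least one seed with at most `floor(k/2)`
mismatches, so enumerating every substitution variant of each seed to that
depth and verifying every candidate window base-by-base returns *all*
placements with Hamming distance <= k (k <= 2). Over-enumeration is
harmless because verification is exact; exhaustiveness is asserted against
a brute-force Hamming scan over every window and strand on randomized
instances. Only the forward strand is stored; minus-strand hits come from
querying the reverse-complemented read, which yields an identical hit set
at half the memory.

Reads shorter than two seeds are unmapped by construction; aligning 20-nt
reads therefore requires `preamble_length <= 10`. The default of 12
balances container occupancy for megabase-scale references.

## Counting rules

Only *best-stratum* alignments are used: perfect placements if any exist,
else 1-mismatch, else 2-mismatch. A unique read is **unambiguous and
usable** when the union of gene loci whose annotated features (exons, UTRs,
CDS, retained introns, junction sequences) overlap its best hits has size
exactly one. A read with several best hits inside one locus — e.g. an exon
hit plus the matching junction hit — counts once per occurrence. Gene
counts add the read's full per-replicate occurrence; isoform counts split
it equally (`o/m`) across the isoforms whose features were hit and are kept
as exact rationals until export, so the gene-level matrix is integral by
construction. The expression filter retains genes with nonzero counts in
every replicate of at least one treatment.

## Quality assessment

Counts are normalized to reads per quarter million, incremented by one, and
natural-log transformed; per treatment, the one-way random-effects
single-rater intraclass correlation ICC(1) = (MSB - MSW) / (MSB + (k-1)MSW)
is computed with genes as rows and the k replicates as raters. The model
choice (one-way, single measure) is fixed for reproducibility; no pass/fail
threshold is enforced — the value is reported for the analyst. MA
coordinates use log2 with a +1 offset on normalized group means so every
point is finite.

## The NBP test

The NBP distribution is a negative binomial whose dispersion depends on the
mean through an extra exponent:

    Var(Y) = mu + phi * mu^alpha,      r(mu) = mu^(2-alpha) / phi,

with `alpha = 2` the classical NB with constant dispersion `phi`.

**Normalization.** Libraries are made comparable by random thinning: every
count in replicate `r` is replaced by a Binomial(count, N/L_r) draw, `N`
the smallest library size. Equal libraries make thinning the identity. One
top-level seed spawns one deterministic substream per replicate
(`numpy.random.SeedSequence`), so results are bit-reproducible. Thinning is
a total-count normalization: it assumes the two treatments have comparable
library composition, and a strongly one-sided DE profile would bias every
null gene (the synthetic generator therefore plants balanced induced and
repressed effects).

**Dispersion estimation.** `(phi, alpha)` are estimated once from all
filtered genes by bounded maximization (L-BFGS-B; alpha in [1.2, 3],
log phi in [-14, 6]) of a Cox-Reid adjusted profile log-likelihood. Each
gene's per-treatment-group mean is profiled out at the group sample mean —
the exact profile MLE of an NB mean, and robust to genuinely differential
genes — and the likelihood is penalized by half the log Fisher information
of every profiled mean (0.5*log of the NBP variance at that mean, dropping
constants). Without the adjustment, profiling out thousands of nuisance
means at 3 replicates per group biases phi downward by roughly the
classical (n-1)/n factor; with it, simulations at (alpha=2, phi=0.1)
recover alpha within ~0.03 and phi within ~10%. The moment estimate of phi
at alpha=2 initializes the optimizer; non-convergence falls back to the
alpha=2 profile with a warning.

**Exact test.** For each gene, the null mean is the pooled mean of thinned
counts over all replicates, giving r = r(mu). Under the null the group sums
are NB with shapes n_A*r and n_B*r and a common success probability, so the
distribution of S_A conditional on S = S_A + S_B is free of that
probability. The conditional pmf is enumerated for s = 0..S; the two-sided
p-value sums all outcomes whose probability does not exceed the observed
one (relative tie tolerance 1e-8; "double the smaller tail" is rejected as
it can exceed 1). S = 0 gives p = 1. Rising factorials
ln G(s+a) - ln G(a) are accumulated as running sums of log(a+i) rather than
as differenced `gammaln` values; this stays exact for the enormous shapes
of the phi -> 0 limit, where the conditional law converges to
Binomial(S, n_A/(n_A+n_B)) and the p-value matches the exact binomial test
to < 1e-9.

**FDR.** Storey q-values: pi0(lambda) = #{p > lambda}/(m(1-lambda)) on
lambda = 0.05..0.95 is smoothed with a cubic polynomial and read off at
lambda = 0.95, clipped to (0, 1]; q-values are the pi0-scaled step-up
values, monotone in p-rank. Below 100 p-values the estimate is unstable and
pi0 is fixed at 1 (exactly Benjamini-Hochberg). The default cutoff is
q <= 0.05.

**Stability of thinning.** `thinning_stability` re-runs thin -> fit -> test
with fresh derived seeds and reports each gene's detection percentage at
the FDR cutoff against the reference run's q-value (binned in 0.005
increments). Detection is near-total for strongly significant genes and
decays toward the cutoff, which is the expected signature of a stochastic
normalization.

## GO enrichment

Annotations are propagated to all ancestors along is_a/part_of edges
(`obonet`/`networkx`; the parent graph must be acyclic). Three tests:
term-for-term (upper-tail hypergeometric against the whole population),
parent-child in the *intersection* variant (the conditioning population is
the genes annotated to all parents of the term; root terms get p = 1), and
a permutation test that redraws the study set uniformly without replacement
(p = (1 + #{m* >= m}) / (n_perm + 1), seeded). Genes missing from the
annotation are dropped from study and population alike. No multiple-testing
correction is applied by default; a BH option exists on each method.

## Synthetic fixtures

The generator emits uniform-random genomes with non-overlapping multi-exon
genes (2-4 exons of 80-220 nt, introns of 40-120 nt; a configurable
fraction gains a second isoform that skips one internal exon), valid GFF3,
NB counts via a Gamma-Poisson mixture with Var = mu + phi*mu^alpha, and
reads drawn uniformly along a uniformly chosen isoform with per-base
mismatch injection capped at 2. The number of reads per gene equals the
drawn count exactly, so counting is checkable by identity; per-read
provenance (gene, isoform, transcript offset, orientation, injected
mismatches, junction crossing) is recorded. Default conditions mirror a
small two-treatment experiment: 3+3 replicates, phi = 0.1, alpha = 2,
per-replicate depth factors drawn in [0.7, 1.3], 25-nt reads, planted DE
at 4-fold split evenly between induced and repressed.

Desk-scale problem sizes used by the test suite and the acceptance script:
2000 genes x (3+3) for null calibration and parameter recovery; 600 genes
for the 100-iteration stability analysis (expression means log-uniform on
[100, 1000], so the planted 4-fold effects are decisively detectable and
the measurement isolates thinning-induced variability rather than
boundary-of-power behavior); a 600-gene, ~0.7-Mb genome at ~60k reads per
replicate for the read-level end-to-end run.

What the fixtures do *not* emulate: sequencing-quality profiles, GC or
positional bias, adapter contamination, paralogous gene families (ambiguity
arises only from chance k-mer collisions in random sequence), unannotated
transcription, and multi-factor designs. Passing tests therefore certify
the algorithmic contracts — exhaustive alignment, exact conditional
p-values, calibrated error control under the assumed NBP model — not
robustness to every artifact of real libraries.

## Known limitations

- The aligner is ungapped and bounded at two mismatches; indels and
  higher-divergence placements are out of scope (junction sequences stand
  in for spliced alignment).
- Thinning discards counts and is sensitive to severe library-size
  imbalance and to one-sided composition shifts; re-sequencing or an
  alternative normalization is advisable in such designs.
- The dispersion fit pools information across all genes into two global
  parameters; per-gene dispersion heterogeneity beyond the mean trend is
  not modeled.
- Isoform counts are bookkeeping (equal splitting), not estimates of
  isoform expression; the pipeline does not infer transcript isoforms.
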