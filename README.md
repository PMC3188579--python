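# seqtally

An RNA-Seq differential-expression pipeline for small designs: exhaustive
short-read alignment over a 2-bit hashed seed index, rule-based gene
counting, replicate quality assessment by intraclass correlation, an exact
negative-binomial test whose dispersion depends on the mean, and GO-term
enrichment — with a synthetic-data generator so the whole pipeline is
testable end to end against known truth.

## Who this is for

Experiments with two treatments and a handful of biological replicates
(n = 2–6 per group) cannot lean on large-sample asymptotics, and Poisson
models understate the variability between biological replicates
(overdispersion). `seqtally` targets exactly this regime: it aligns reads
exhaustively, derives gene counts under explicit ambiguity rules, and tests
each gene with an exact conditional test under an overdispersed count
model, sharing dispersion information across genes.

## The model

Counts follow an over-parameterized negative binomial (NBP) whose variance
depends on the mean through an extra exponent:

    Var(Y) = μ + φ·μ^α        (α = 2 ⇒ classical NB, dispersion φ)

Libraries are normalized by **random thinning**: each library is binomially
downsampled to the smallest library size, so totals are comparable without
scale factors and an exact test applies. The global parameters (φ, α) are
estimated from all filtered genes by a Cox–Reid adjusted profile
likelihood; each gene is then tested with the exact conditional test: with
NB size r = μ^(2−α)/φ, the group sums are NB(n_A·r) and NB(n_B·r) under the
null, and the distribution of one group's sum given the total is enumerated
exactly. The two-sided p-value sums all outcomes no more likely than the
observed one; Storey q-values control the FDR (default q ≤ 0.05).

## Worked example

Generate a synthetic experiment (30 genes, 3+3 replicates, 10% of genes
differentially expressed at 4-fold, overdispersion φ = 0.1) and run the
pipeline:

```sh
seqtally synth --out-dir demo --n-genes 30 --length 50000 \
    --depth 4000 --seed 3
seqtally --store demo.db build-ref --fasta demo/genome.fasta \
    --gff3 demo/annotation.gff3 --flank 24
seqtally --store demo.db load-reads --manifest demo/manifest.tsv
seqtally --store demo.db align --max-mismatch 2
seqtally --store demo.db count
seqtally --store demo.db assess
seqtally --store demo.db dge --seed 1 --fdr 0.05
```

Output of the run above:

```
catalog: 30 genes, 86 intervals, 62 junctions, 0 rejects
11779 unique reads from 23513 raw reads
12199 alignments; 11779/11779 unique reads mapped
11779 unambiguous unique reads; matrix 30 genes x 6
ICC[mock] = 0.8851
ICC[treated] = 0.8971
alpha = 1.690, phi = 0.3377; 1 induced, 2 repressed at FDR <= 0.05
```

Reading it: every synthetic read aligned and was unambiguous and usable
(each touches a single gene locus), and per-treatment ICC values around
0.89 indicate well-agreeing replicates on the log scale. With only 30 genes
the global dispersion fit is rough (it pools across genes; 2000-gene
simulations recover φ within ~10%), but the exact test still calls exactly
the three planted DE genes with the correct directions:

```
   gene_id  fold_change       q_value  direction
4    g0005     5.666667  2.571039e-07    induced
15   g0016     0.220615  7.798910e-13  repressed
17   g0018     0.312715  2.133596e-05  repressed
```

`seqtally --store demo.db export dge --out results.tsv`
writes the per-gene table (counts, normalized means, fold change, p, q,
direction); `export alignments` emits SAM, `export counts` the count-matrix
TSV.

A precomputed count matrix can skip the alignment stages entirely:
`seqtally dge --counts-tsv matrix.tsv --seed 1`. GO enrichment of the
significant set runs with `seqtally go --obo terms.obo --annotations
gene2term.tsv --method parent_child`, and the repeat-thinning stability
analysis with `seqtally stability --iters 100 --out stability.tsv`.

The same steps are available as a library (`seqtally.pipeline.run_pipeline`,
`seqtally.dge.nbp_test`, …) — see `docs/methods.md` for the full model
description and the numerical choices.

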