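# wescover

Breadth-of-coverage QC for whole exome sequencing (WES), and a decision aid
for choosing between WES and targeted gene panel testing.

## The problem

WES does not capture every coding exon equally well: capture-bait efficiency
varies, so some exons of clinically implicated genes are left with too few
reads to call variants reliably even when the sample's *average* read depth
looks fine.  An absent variant in such a gene may simply be a false
negative.  Clinicians and researchers therefore need, per gene, a measure of
how completely its coding sequence is covered — and, when coverage is
inadequate, a pointer to registered targeted gene panel tests that cover the
gene.

## The metric

For a transcript with coding positions *p₁ … p_L* (CCDS exon models, merged
so no base is double-counted) and a per-locus depth threshold *t*, the
**breadth of coverage** is

    B(t) = |{ p : depth(p) ≥ t }| / L

i.e. the fraction of coding bases supported by at least *t* reads.  A 300-bp
coding sequence with 270 positions at depth ≥ 10 has B(10) = 0.90 (90%).
B(t) is non-increasing in *t* and is evaluated on the standard ladder
5×, 10×, 15×, 20×, 25×, 30×, 50×, 100× (default decision threshold 20×,
sufficient for ~99% SNV sensitivity).

Across a cohort with population labels (e.g. AFR/AMR/EAS/EUR/SAS), the
package reports per-transcript global mean/min/max breadth, per-population
means, and three formal comparisons across populations: one-way ANOVA,
pairwise two-sample Kolmogorov–Smirnov, and Tukey's HSD.  It also computes
the complementary per-locus cohort metric — at each coding position, the
fraction of samples with depth ≥ t (the gnomAD-style coverage summary); the
gene-level mean of that metric equals the sample-mean breadth exactly, since
both average the same sample × position indicator matrix.

Finally, a registry of genetic tests (GTR-style TSV linking tests to
phenotypes, HPO terms and genes) can be queried by gene symbol, phenotype
substring or panel name, and transcripts whose cohort mean breadth falls
below an adequacy cutoff (default 0.90) are flagged `consider_panel` with
every registered test covering the gene attached.

## Worked example

Simulate a small stratified cohort, compute breadth, summarize and get
recommendations:

```sh
wescover simulate --out demo --seed 7 --genes 5 --pops AFR,EUR --n 4 \
    --mean-depth "AFR=60,EUR=25"
wescover compute --models demo/models.bed12 --models-format bed12 \
    $(for f in demo/depth/*.bedgraph; do echo --depth $f; done) \
    --out demo/breadth.tsv
wescover summarize --breadth demo/breadth.tsv --samples demo/samples.tsv \
    --threshold 20 --out demo/summary.tsv
wescover recommend --summary demo/summary.tsv --registry demo/registry.tsv \
    --threshold 20 --cutoff 0.9 --out demo/recs.tsv
```

`demo/summary.tsv` (rows ascend by global mean, worst-covered first):

```
gene_symbol  ccds_id  threshold  global_mean   global_min   global_max  mean_AFR      mean_EUR      anova_F      anova_p
GENE2        CCDS2.1  20         0.6638489209  0.3683453237 1           0.8143884892  0.5133093525  5.164368751  0.06344740278
GENE1        CCDS1.1  20         0.6888835419  0.0384985563 1           0.8902791145  0.4874879692  5.688021823  0.05439902376
GENE4        CCDS4.1  20         0.7259402655  0.4933628319 1           0.8973082596  0.5545722714  51.11166274  0.0003775974019
...
```

Reading the first row: across the 8 simulated exomes, on average only 66.4%
of GENE2's coding bases reach 20 reads (one sample as low as 36.8%), the
AFR group is better covered than EUR (81.4% vs 51.3%), and the ANOVA does
not quite reject equality of population means at α = 0.05 (p = 0.063).
Since 0.664 < 0.90, `demo/recs.tsv` flags GENE2 as `consider_panel` and
lists the registered tests covering it (`GTR000003|GTR000004|GTR000011`).
Pairwise KS and Tukey results are written alongside as
`demo/summary.tsv.pairwise.tsv`.

The same pipeline runs on real data: CCDS text dumps or BED12/BED6 gene
models, per-sample BedGraph or samtools-depth TSV depth files, a two-column
sample sheet and a registry TSV (schema in `docs/methods.md`).

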