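# Methods

## Coordinate conventions and gene models

All genomic coordinates are stored 0-based, half-open (`[start, end)`), the
BED convention, with a single conversion at each parser boundary:

* **CCDS text dumps** list `cds_locations` as 0-based inclusive-inclusive
  `from-to` pairs; `to` is incremented on parse.  Only rows whose
  `ccds_status` is in the accepted set (default `{"Public"}`, configurable)
  are kept; withdrawn rows (`cds_locations == "-"`) are skipped; duplicate
  CCDS ids are an error.
* **BED6/BED12** follow the UCSC conventions unchanged; BED12
  blockStarts/blockSizes are expanded relative to chromStart, and BED6 exon
  rows are grouped into one transcript per name.
* **samtools-depth TSV** positions are 1-based and shifted on read.

Chromosome names are normalized by stripping a leading `chr`, so GRCh37- and
GRCh38-styled files interoperate; the assembly itself is carried only as a
free-text tag.  Within a transcript, exons are merged (overlaps unioned,
adjacent intervals coalesced) before any computation, so breadth is always
a proportion of *distinct* coding positions.  Strand is carried but ignored
by all coverage arithmetic — depth is strandless.

## Depth representation

Per-sample depth is held as run-length intervals `(start, end, depth)` per
chromosome, sorted and non-overlapping, with absence meaning depth 0.  This
keeps cohort × exome-scale data in memory at desk scale; only the
position→depth function is contractual (run boundaries are not), and the
canonical writer coalesces equal-depth adjacent runs.  Queries against a
transcript (`depth_over`) return runs that partition the queried bases
exactly, materializing depth-0 gaps, so every downstream computation
conserves base counts by construction.

The package takes depth files (BedGraph or samtools-depth TSV) as given and
does not compute depth from BAM/CRAM alignments; whatever MAPQ/base-quality
/overlapping-mate filtering produced the depth files is upstream of this
tool and should be reported with it.

## The breadth metric

`breadth(t) = |{coding p : depth(p) ≥ t}| / coding_length`.  The covered-
locus comparison is `≥ t` — a locus with exactly *t* reads counts as
covered — with a `gt` switch retained purely for auditability.  Fractions
are kept at full precision internally; rendering as percentages is
presentation-only.  The multi-threshold profile is computed in one pass
over the depth runs and is non-increasing along the ladder by construction.
The default ladder is 5, 10, 15, 20, 25, 30, 50, 100 (×); the default
decision threshold is 20×, a level commonly cited as sufficient for ~99%
SNV detection sensitivity.

## Cohort summaries and comparison tests

Per (transcript, threshold) the summary holds the arithmetic mean, minimum
and maximum of per-sample breadths (min/max are per-sample extremes, not
population-mean extremes) plus per-population means; report rows ascend by
global mean so the worst-covered transcripts lead.  Three comparisons run
on the per-sample breadth values across population groups:

* **One-way ANOVA** (`scipy.stats.f_oneway`): fixed effects, F on
  (k−1, N−k) degrees of freedom.
* **Kolmogorov–Smirnov**, all pairs (`scipy.stats.ks_2samp`), asymptotic
  p-values by default (groups are large in intended use); pairs with a
  singleton group are flagged `unreliable`.
* **Tukey's HSD**, all pairs, computed directly from the studentized range
  distribution with the pooled within-group variance (the Tukey–Kramer
  standard error for unequal group sizes).  This in-package computation
  exists because singleton groups must degrade gracefully rather than
  raise; it is cross-checked in the tests against the k = 2 closed-form
  collapse (adjusted p equals the unadjusted equal-variance t-test p).

Degenerate inputs — every observation identical, or too few observations to
estimate within-group variance — return flagged NaN results instead of
raising, so exome-wide batch runs never abort on the (common) transcripts
with breadth exactly 1.0 in every sample.  No multiple-testing correction
is applied across genes; the table reports raw p-values, and users
comparing many genes should correct downstream.

Tests are computed at the user-selected threshold; `summarize
--all-thresholds` computes them at every ladder rung.

## Per-locus cohort metric

`locus_fraction` computes, at each coding position, the fraction of cohort
samples whose depth meets the threshold — the same quantity large public
aggregation databases publish as their coverage summary.  Its gene-level
mean and the sample-mean breadth are two marginalizations of one indicator
matrix (samples × positions) and agree to floating-point identity; the test
suite asserts agreement to 1e-12.  An importer for a 2-column
`position<TAB>fraction` TSV lets externally published per-locus summaries be
displayed alongside cohort-computed ones.

## Panel registry and recommendations

The registry TSV has columns `test_id`, `test_name`, `clia_certified`,
`gtr_phenotypes`, `hpo_terms`, `gene_symbols`; list-valued columns are
`|`-delimited and HPO terms are written `HP:NNNNNNN=Label`.  Rows with a
malformed HPO id or an empty gene list are rejected (counted and warned);
duplicate test ids are an error.  Gene queries are exact case-insensitive
symbol matches; phenotype and panel-name queries are case-insensitive
substring matches (no HPO ontology reasoning — literal terms only), with
genes deduplicated and returned in lexicographic order.

A transcript is flagged `consider_panel` iff its cohort mean breadth at the
chosen threshold is **strictly below** the adequacy cutoff; a mean exactly
at the cutoff is adequate.  The default cutoff is 0.90, anchoring on the
convention that > 0.9 marks the well-covered regime; both cutoff and
threshold are configurable.  Flagged genes carry every registered test
covering them; flagged genes with no registered test are marked
`no_panel_available`.  Recommendations are a deterministic function of
(summary, registry, threshold, cutoff).

## Synthetic cohorts

The generator fabricates gene models, per-sample depth tracks, sample
sheets and registries in exactly the dialects the readers consume.  The
depth model works at the exon level: each sample draws a per-exon mean from
a gamma mixture around the population's capture mean (negative-binomial-
style overdispersion), renders it piecewise-constant in ~20-bp chunks with
±10% uniform jitter, and zeroes the whole exon with a per-exon dropout
probability.  Defaults — mean depth 60×, dispersion 0.3, dropout 0.02,
five populations (AFR, AMR, EAS, EUR, SAS) — are chosen once as realistic
WES capture behaviour and reproduce the phenomenon the metric targets:
individual exons left uncovered while average depth is high.

What the simulator does **not** emulate: GC/sequence-context coverage
bias, read-level noise, mate-pair structure, shared bait design across
samples (exon failures are independent per sample), or reference-assembly
differences.  Passing tests on synthetic cohorts therefore demonstrate the
arithmetic, the statistics and the plumbing — not that any particular real
capture kit is well behaved.

Every sample derives its own random stream from `(seed, crc32(sample_id))`,
so adding or removing a sample never perturbs the others, and the same seed
yields byte-identical output files.

## Numerical choices and edge cases

* Breadth is exact rational arithmetic (integer base counts divided once);
  the dense per-base counting oracle in the tests must agree *exactly*, not
  approximately.
* A transcript with zero coding length cannot form a proportion and is an
  error at parse/construction time (models are required non-empty).
* Overlapping BedGraph lines are an error naming the first collision;
  non-monotone samtools-depth positions are an error.
* Problem sizes in the test suite — spans up to a few kb, cohorts of tens
  of samples, 1000-replicate null simulations — are chosen so the whole
  suite completes in seconds while still exercising every contract at
  desk scale.

## Known limitations

Breadth is not normalized for GC content or sequence context, so comparing
values *between* genes conflates capture design with sequence difficulty.
The tool is gene/transcript-level only: it does not locate specific
poorly-covered sub-regions or variants within a gene.  Panel matching is
literal string matching against a registry snapshot; it performs no
ontology closure and a registry TSV must be supplied (live registry
retrieval is out of scope).
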