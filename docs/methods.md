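# Methods

This note documents the models, conventions and design choices behind the
package, in the order data flows through the pipeline.

## Tag definition and the in-silico digest

A tag is a fixed 27-mer: the NlaIII recognition site CATG plus 23
downstream bases. Real library construction (EcoP15I release) produces
slight length variability; we ignore it and treat every tag as exactly
27 bp, which is also how the tags are counted. The canonical tag of a
transcript is anchored at the most 3′ CATG that has at least 23 downstream
bases and no ambiguity code in the window. Two non-obvious conventions:

- **Truncated 3′ ends.** If the most 3′ CATG has fewer than 23 downstream
  bases, we fall back to the next eligible CATG upstream rather than
  declaring the transcript tagless. On intact cDNA the poly(A) tail
  supplies downstream bases, so the fallback only fires for truncated
  references, where a usable tag beats none. Transcripts with no eligible
  site are listed separately by the digest and reported as a fraction.
- **N handling.** Windows containing N are skipped with the same fallback:
  tags are observed sequences and ambiguity codes cannot be counted.

Coordinates are 0-based half-open internally; TSV outputs use 1-based
positions.

## QC filters

Two rules, applied in order per tag, in tag-count units:

1. *Anchor*: the tag must begin with CATG (strict prefix test). Failures
   are adaptor-ligation artifacts.
2. *Poly-A runoff*: the maximal terminal run of A must be ≤10. "Greater
   than 10 As" is read as a terminal homopolymer run, not total A content,
   because the filter targets poly(A)⁺ runoff, which is terminal.

Tags containing N fail QC; they are tallied inside the anchor-failure
column (with a separate sub-count) unless a disqualifying A run removes
them first. The accounting invariants — total = with-anchor + removed, and
with-anchor = potential-mappable + poly-A-removed — are enforced by the
`QCReport` constructor and property-tested, and filtering is idempotent.

## Mapping model

Matching is *anchored*: candidate positions are exactly the CATG sites
with ≥23 downstream bases, on the given strand and on the reverse
complement, and the 2-mismatch budget applies to the 23 non-anchor bases
(the anchor must match exactly). Rationale: tags can only arise at NlaIII
sites biologically, and anchoring bounds the search space. The
implementation encodes all candidate windows as a byte matrix and computes
blocked vectorized Hamming distances; its contract is equivalence with an
exhaustive both-strand window scan, which the test suite checks on
hundreds of randomized instances.

Partition assignment is simultaneous best-distance, not two sequential
passes: a tag hitting only plant references at its minimal distance is
plant, only fungal is fungal, both at equal distance is *ambiguous* and
excluded from both partitions (including normalization denominators).
Order-dependent two-pass mapping would silently bias attribution toward
whichever reference is mapped first.

Quantification is per distinct tag sequence. A tag whose best hits touch
several transcripts within one partition keeps a single count annotated
with all best hits (mirroring how allelic SNP tags of one protein are
treated); counts are never split. Antisense calls require oriented
references; hits on non-oriented references are reported strand-unknown.

## Normalization and differential expression

Plant tags are scaled to tags per million plant-mapped tags per replicate
(the SAGE sense of "TMM" — simple library-size scaling, not the
trimmed-mean-of-M-values method). Fungal tags are scaled to percent of
fungal-mapped tags, which is better conditioned for a partition of only a
few thousand counts. Each partition's denominator excludes the other
partition and ambiguous tags.

Differential expression uses a two-sided pooled-variance Student's t-test
per tag on normalized values (df = nA+nB−2 = 4 at 3+3), flagged at raw
P < 0.05 with no multiple-testing correction — reproducing the original
analysis convention first; a Bonferroni option exists but is off by
default. Welch's test is available via `equal_var=False`. Degenerate
cases: both groups constant and equal gives (t=0, p=1); both constant and
unequal gives p→0 and a `degenerate` flag. With substitution errors in the
libraries, rare error-derived tags (e.g. one count in each replicate of
one sample, zero in the other) land in this degenerate class, so the raw
count of flagged tags overstates the biological signal; the flag lets
consumers filter, and the simulation metrics below are computed on
canonical tags only.

Fold changes are signed ratios of group means: +R when the infected
sample is higher, −R when lower, +1 at equality. When one group mean is
zero, it is floored at half the smallest nonzero normalized value in the
matrix and the row is flagged `floored`; both-zero tags are untestable and
dropped.

Report percentages round half away from zero (so 12.5% prints as 13%):
integer percent for plant-style numbers, one decimal for fungal mapped
fractions, two decimals for fungal abundance percents.

## Fungal ranking and antisense ratios

Abundant fungal tags are those at or above 0.01% of fungal mapped tags
(mean of per-replicate percents over the infected sample's replicates),
ranked descending with cumulative share. Antisense pairing is per
transcript: any tag mapping to the reverse complement at an anchored site
counts as antisense evidence for that transcript, whether or not it is the
reverse complement of the sense canonical tag (the strands generally
anchor at different CATG sites). The ratio is reported as 1:N with
N = round(sense/antisense) on mean normalized abundances; transcripts with
antisense but no sense signal are emitted flagged antisense-only.

## The synthetic-data generator

Defaults encode the study conditions the pipeline is meant to operate
under; they are fixed, not tuning knobs.

| parameter | default | why |
| --- | --- | --- |
| replicates | 3 + 3 | biological triplicates per sample |
| library_size | 100,000 | desk-scale stand-in for the 5–10 M-tag libraries; large enough for the recovery metrics below |
| n_plant_transcripts / n_de | 1050 / 50 | 1000 null tags plus 50 truly-DE tags |
| de_fold / within_group_cv | 4.0 / 0.20 | planted effect size and biological noise |
| fungal_fraction | 0.02 | fungal biomass and mapped-tag share are both ≈2% |
| fungal_top_share | 0.10 | the top fungal transcript carries ~10% of fungal tags |
| antisense_ranks | {1: 9, 4: 87} | sense:antisense 1:9 at the top transcript, 1:87 at rank 4 |
| no_anchor_rate | 0.30 | ~30% of raw tags lack the anchor in real libraries |
| polya_runoff_rate | 0.002 | observed attrition at the poly-A filter is ~0.2% |
| error_rate | 0.01/base | substitution errors on the 23 non-anchor bases |
| polya_tail | 30 nt | guarantees downstream bases for 3′-proximal sites |
| length mean/sd, GC | 500/150 bp, 0.50 | typical assembled-EST scale; uniform base usage gives the 1/256 CATG density |

Mechanics worth knowing:

- Transcript bodies are rejection-sampled so every emitted transcript
  yields a QC-passing canonical tag (and an anchored reverse-complement
  site where antisense is planted); the digest of the generated reference
  *is* the truth catalog.
- Plant abundances are log-normal (μ=0, σ=1); fungal abundances follow a
  Zipf law whose exponent is solved numerically so the top transcript
  takes the configured share. Fungal tags are present only in the
  infected sample.
- Libraries are multinomial draws at fixed size (SAGE counts a fixed
  number of tags), not Poisson.
- Within-group variability is multiplicative gamma noise (mean 1, CV
  0.20). Plant species vary independently — this is what the t-test must
  ride over. Fungal species share one factor per replicate, emulating
  replicate-to-replicate biomass differences (the dominant source of
  fungal variation in real infected tissue, and visible there as mapped
  fungal fractions ranging ~1.4–2.8%); percent-of-mapped normalization
  cancels a shared factor, keeping within-fungus proportions stable.
- Substitution errors are applied after tag extraction (sequencer stage),
  uniformly over the 23 non-anchor bases; anchor-broken tags are governed
  separately by the no-anchor artifact rate.

What the simulation does *not* emulate: incomplete references (every
simulated tag has a true source, so plant mapping rates are ~100% rather
than the 37–60% seen with a partial reference), platform-specific
color-space error profiles, non-uniform base composition, 3′-bias, and
gene families sharing near-identical tags. Passing recovery tests
therefore demonstrates correctness of the counting, mapping and testing
machinery under the stated generative model — not robustness to reference
incompleteness or real error structure.

## Recovery metrics and expected variability

The reproduction script (`scripts/acceptance.py`) measures the mean CATG
spacing on 4 Mb of seeded uniform random sequence — the estimator's SD is
~1.5% per Mb, and 4 Mb brings it under 1% at negligible cost (the test
suite exercises the same check at 1 Mb). On a default-scale run the pipeline is scored against truth: DE power
(fraction of the 50 planted tags flagged), empirical type-I error (flagged
fraction of the 1000 null canonical tags; expected ≈5%), recovery of the
top-5 fungal ranking order, and the planted 1:9 antisense ratio. At 10⁵
tags per library the fungal partition holds only ~1,400 tags per
replicate, so two metrics are inherently noisy across seeds: adjacent
fungal ranks differ by ~15–25% with ~10% counting noise (occasional
adjacent swaps in the top 5), and the pooled antisense count (~50 tags)
gives the recovered N a standard deviation of roughly 1.3. The fixed-seed
test run recovers 5/5 and 1:9 exactly; other seeds can land one rank swap
or one unit of ratio off without indicating a defect. The rank-4 1:87
antisense species (~1 expected count) is usually unsampled and reported as
missing.

## Numerical and interface choices

- Ties in report rounding go away from zero (`round_half_away`), because
  banker's rounding contradicts printed report conventions.
- The t statistic and p-value come from the closed-form pooled test plus
  the t distribution CDF; scipy's `ttest_ind` is used only as an
  independent oracle in the tests.
- Mapping is deterministic and invariant to tag input order; all
  randomness in the simulator flows from one integer seed through named
  substreams, so identical seeds give byte-identical outputs.
- The per-module operations are the primary interface; the CLI wraps them
  thinly (`digest`, `qc`, `map`, `simulate`, and an end-to-end `run` that
  chains simulation, analysis and reporting). Report tables are TSV plus
  one plain-text summary, keeping outputs diffable; the report builder
  recomputes and cross-checks QC conservation and partition sums, raising
  `ReportConsistencyError` rather than emitting inconsistent tables.
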