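# Methods

`sbscreen` analyzes Sleeping Beauty (SB) transposon insertional-mutagenesis
screens with paired tumor compartments (primary tumors and metastases). This
note describes the models and procedures each stage implements, the
parameters that matter, what the synthetic-screen generator does and does
not emulate, and the numerical choices made where the design was open.

## Insertion calling

SB transposons integrate into TA dinucleotides. An insertion call is the
0-based forward-strand position of the T of that TA, plus the transposon's
orientation relative to the forward strand. A single unambiguous address per
event is what makes cross-sample identity (the basis of the clonality module)
exact; insertions at one TA in the two orientations are distinct records.

Read 1 of a splinkerette ligation library is
`[8 nt barcode][26 nt transposon-end adapter][genomic sequence]`. Trimming
is 5'-anchored with no indels and, by default, no mismatches (synthetic reads
are error free; a substitution allowance is configurable for real data), and
reads whose trimmed suffix is shorter than 5 nt or whose genomic part does
not begin with TA are discarded. Demultiplexing is an exact barcode lookup
in a manifest, not error-tolerant matching.

Alignment of the error-free synthetic reads uses an exact-prefix index
(first k = 25 bases, both strands); a read with anything other than exactly
one hit across both strands is discarded as multimapping — conservative and
deterministic. Pre-aligned SAM/BAM is accepted as an alternative input, the
TA address being the leftmost aligned base (forward) or `reference_end − 2`
(reverse). The aligner is deliberately minimal: the contract that matters
downstream is "unique best hit → TA address", not alignment sensitivity.

Identical (sample, library, chrom, ta_pos, orientation) reads are grouped
into calls with `read_count` = group size. The two transposon-end libraries
(IRL/IRR) are merged per sample by union over addresses, keeping the higher
read count where an address is seen in both.

## Dynamic clonal/subclonal filter

Per sample × library, three thresholds are computed from the per-site read
counts:

1. `nb_q95` — the 0.95 quantile of a negative binomial fitted to the counts
   by method of moments (size r = m²/(v − m)); when v ≤ m (no
   overdispersion, e.g. all counts equal) a Poisson with the same mean is
   used. A maximum-likelihood fit is available behind `nb_fit="mle"`;
   moments is the default because it is closed-form and deterministic.
2. `top1pct` — the count at rank ⌈0.01 n⌉ from the top, i.e. the smallest
   count inside the top-1% most abundant sites.
3. `frac_total` — 0.001 × total reads in the library, kept real-valued.

The clonal cutoff is the most stringent (largest) of the three; the
subclonal cutoff is the second-most stringent, operationalized as the median
of the three (the forced reading of a three-value ranking, ties included).
Counts equal to a cutoff belong to the higher class: the quantile wording is
ambiguous at the boundary and the inclusive rule is deterministic.
Thresholds are computed per library *before* merging; a merged address
present in both libraries keeps the stricter (lower) of its two labels,
while its read count keeps the higher value. "filtered_clonal" data are the
clonal class only; "filtered_subclonal" are clonal ∪ subclonal.

The filter presumes clonal insertions are rare relative to the library's
site count — in particular rarer than the top-1% rank. That matches real
screen libraries (thousands of background sites, a handful of selected
clones) and the simulator's defaults are chosen in the same regime (see
below).

## gCIS statistics

Under neutral integration, a gene's expected share of the cohort's
insertions is its share of the genome's TA sites:

    expected = n_insertions_cohort × ta_in_gene / ta_genome.

Gene territory is the transcript span by default (a strand-aware upstream
promoter window can be added by flag). Observed counts are insertion
records, not samples; per-sample recurrence is reported separately as
`samples_hit`. The test is one-sided enrichment only (observed ≤ expected
gives p = 1): CIS discovery has no meaningful depletion alternative.

The default p-value is the exact binomial upper tail
P(X ≥ observed), X ~ Binomial(n, ta_in_gene/ta_genome). A chi-square path
((obs − exp)²/exp, 1 df, upper tail halved for one-sidedness) is available
behind a flag, itself reverting to the exact test when expected < 5. The
normal approximation is noticeably off in the tail even for expected ≥ 20
(relative p-value error up to ~25% at p ≈ 0.05, ~12% at p ≥ 0.2), which is
why the exact path is the default everywhere.

Before testing, each screen arm's donor-concatemer chromosome is excluded:
local hopping concentrates re-integrations near the donor site, so donor
chromosome insertions of that arm's samples are removed and genes on donor
chromosomes are skipped; the TA background `ta_genome` is likewise summed
over non-donor chromosomes. Multi-copy artifact genes (the Sfi1 class,
recurrently hit in SB screens because of genomic copy number rather than
selection) are excluded by blacklist. Bonferroni correction uses
m = number of genes actually tested (TA-containing, not excluded);
significance is adjusted p < 0.05. Genes with no TA sites are reported
untestable with p = 1. Results order is (p_adj, gene name), so output is
deterministic under ties.

## Compartment classification

Set algebra over the two compartments' significant clonal gCIS genes:
significant in primary only → P-specific, metastasis only → M-specific,
both → shared (S-driver). At the subclonal level, a compartment-specific
gene with ≥ 1 filtered-subclonal insertion in the other compartment (in any
sample; no significance requirement) is relabeled "P-enriched"/"M-enriched".
The label set {P-specific, P-enriched, M-specific, M-enriched, shared} keeps
the specific/enriched distinction visible; relabeling never removes a call.

## Clonality

For every (primary, metastasis) pair within one animal, the shared sites are
the exact intersection of (chrom, ta_pos) addresses in the filtered-subclonal
tables. Orientation agreement is reported as a QC fraction but not required
for a match — a site is identified by its nucleotide interval. A single
exact TA-resolution match (min_shared = 1) is treated as clonal evidence;
read-count concordance is not used. Metastases sharing no site with any
primary biopsy of their animal are flagged unassigned, distinguishing
"no primary biopsied" from "no shared sites". Pairs are never formed across
animals.

## Pathway activity

Activity of a gene signature in a sample is the mean per-gene z-score
(z-scored across samples; a zero-variance gene contributes 0) min-max
rescaled to [0, 1] across the cohort, placing ΔMean (metastasis − primary
mean activity) on a 0–1 heat-map scale. A degenerate cohort with no spread
scores 0.5 by convention. This mean-z scoring is this package's own choice
of a simple, deterministic surrogate for regression-based signature scores;
whether a fixed ΔMean robustness threshold transfers exactly between scoring
schemes is a calibration caveat to keep in mind with real cohorts.

Comparison per pathway is a two-tailed Welch (unequal-variance) t-test —
cohorts are typically unbalanced — with a paired t-test behind a flag.
Classification is a conjunction: M-enriched requires p < alpha (default
1e-4) *and* ΔMean > delta_threshold (default 0.27); P-enriched symmetric
with ΔMean < −0.27; everything else shared. A compartment with < 2 samples
yields an undefined p and a flagged "shared".

## Synthetic screen generator

The generator emulates a two-compartment SB screen with known ground truth:

- **Genome**: 4 chromosomes × 150 kb of i.i.d. A/C/G/T (TA density ≈ 1/16),
  80 non-overlapping genes of 2–6 kb with 1–5 exons and random strand; every
  gene is guaranteed ≥ 20 TA sites (locally resampled otherwise). RefFlat,
  FASTA, TSV and FASTQ outputs are byte-deterministic under a fixed seed.
- **Cohort**: 40 primary tumors (one animal each) and 30 metastases, each
  metastasis descending from a uniformly chosen parent primary.
- **Drivers**: 5 primary-specific, 5 metastasis-specific and 4 shared
  planted driver genes, placed off the donor chromosome; each sample hits
  each compartment-appropriate driver with probability 0.8 at a random TA
  inside the gene. A multi-copy-like artifact gene ("Sfi1like", also
  off-donor) is hit in 60% of samples of both compartments, emulating the
  copy-number-driven recurrent artifact of real screens at the insertion
  table level (its sequence is not actually duplicated).
- **Counts**: negative binomial per insertion and library — clonal mean 300
  (dispersion 5), subclonal background mean 10 (dispersion 2), truncated at
  1. Every event appears in both IRL and IRR with independent counts except
  a 10% single-library fraction. 2000 background insertions per sample at
  uniform-random TA sites keep clonal events well below 1% of a library's
  sites, the regime the three-threshold filter presumes.
- **Local hopping**: background density on the donor chromosome (chr1) is
  multiplied 5-fold.
- **Inheritance**: each metastasis copies each of its parent's clonal
  insertions with probability 0.5 at the identical coordinate, then adds its
  own M/S-driver hits and background. Inherited coordinates are the planted
  shared-site truth for the clonality module. A consequence worth noting:
  inherited primary-driver insertions make some P-drivers significant in the
  metastasis cohort too, so planted P-drivers may legitimately classify as
  shared — the recovery guarantees are stated for shared and M drivers and
  for per-compartment significance.
- **Reads**: read 1 = barcode + adapter + 50 nt of genomic sequence starting
  at the TA in the transposon's direction; read 2 is a downstream fragment
  used only as alignment confirmation; qualities are constant. Planted
  sites keep a 200 bp margin from chromosome ends so every read fits; the
  emitter skips (with a warning) any site that would not.

Not emulated: sequencing errors, PCR duplicates, quality-score structure,
chimeric reads, real TA-site clustering, copy-number or purity effects on
read counts, and real barcode cross-talk. Passing tests therefore
demonstrate correctness of the analysis contracts, not robustness to
real-library noise; the SAM ingestion path and the configurable mismatch
allowance are the entry points for real data.

The expression-cohort generator plants additive mean shifts (default ±0.5,
Gaussian noise sd 0.2, 50 samples per compartment) on disjoint signature
gene sets over a background of unshifted genes, with the ground-truth class
recorded. It emulates a normalized log-expression matrix; it does not
emulate gene–gene correlation or batch structure.

## Problem sizes used in checks

The packaged checks run the default 70-sample screen (~260 k insertion
records) for driver recovery and clonality, twenty 15-sample null screens
(no planted drivers) for family-wise error, forty 100-sample expression
cohorts for pathway-classification accuracy, and a 7-sample read-level
screen (~12 k reads) for the FASTQ round-trip identity. These sizes give
stable recovery estimates while keeping a full run in the tens of seconds.

## Known limitations

- The exact-prefix aligner requires error-free reads; real libraries must
  come in through the SAM path.
- Negative-binomial fitting is per-library on per-site counts; with very few
  sites (< ~100) the top-1% rank and the NB quantile interact poorly and the
  filter degenerates (everything subclonal or discarded) — by design the
  filter is a cohort-scale tool.
- The gCIS background model treats all TA sites as equally accessible;
  chromatin or replication-timing biases of real genomes are not modeled.
- Bonferroni across tested genes is stringent; no FDR alternative is
  currently exposed.
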