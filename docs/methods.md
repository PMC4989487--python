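# Methods

## Scope and data model

`editscan` detects RNA-editing sites by contrasting coordinate-sorted
RNA-seq alignments with matched DNA-seq alignments over a reference
genome. Pre-aligned SAM/BAM is the supported entry point; the package
does not run a read mapper. The per-site unit is a stack of base
observations (base, Phred quality, read footprint and cycle), built
separately for the DNA and RNA layers; every downstream statistic
consumes these stacks.

All external coordinates are 1-based inclusive (SAM/GTF convention).

## Read hygiene

* **Uniqueness.** When the aligner reports best/suboptimal hit counts
  (BWA `X0`/`X1`, or `NH`), a read is kept only with exactly one best
  hit and no suboptimal hit; otherwise a MAPQ floor (default 20)
  applies, with a logged notice.
* **Duplicate collapse.** Reads (for pairs, pairs) sharing an identical
  mapping footprint are collapsed to the single member with the highest
  MAPQ, ties broken by read id so the result is independent of input
  order.
* **End clipping.** The first and last `clip_n` (default 6) cycles of
  every read are masked at pileup time rather than rewritten, so the
  realignment filter still sees the original sequence. Read ends carry
  elevated error from random-hexamer priming and indel mishandling.
* **Base quality.** RNA bases below Q30 are dropped, capping per-base
  error among retained bases at `10^(-30/10) = 0.001`. DNA pileups use
  a milder default floor (Q20) since the genotype likelihood already
  weights bases by quality.

## Junction library and lift-over

Junction contigs concatenate the last `read_length − 1` exonic bases
upstream and the first `read_length − 1` downstream of each distinct
splice junction — short enough that no read can hit both the genome and
the contig. Flanks truncated by short exons or contig edges are
emitted truncated and flagged; flanks are not concatenated across
multiple exons. Contig offsets lift to genomic coordinates by
`g = left_exon_end − (flank − offset)` on the left flank and
`g = right_exon_start + (offset − flank − 1)` on the right; lifted
alignments carry an `N`-gap CIGAR. Junction alignments that do not span
the midpoint duplicate the genomic hit and are dropped.

## Genotype models

The genotype space for ploidy `p` holds the 4 homozygotes plus every
biallelic composition of the 6 unordered base pairs: `6p − 2` genotypes
(10 at `p = 2`, 22 at `p = 4`, 46 at `p = 8`). Restricting to at most
two distinct alleles is what makes the space linear in ploidy; it is
also the only enumeration consistent with those counts.

* **Bayesian (default).** `P(b|g) = Σ_{a∈g} (n_a/p)·[(1−e) if a=b else
  e/3]` with `e` from the base quality; the posterior uses a uniform
  prior over the space by default. A heterozygote-downweighted prior
  (relative mass 0.001 per heterozygous genotype) is available; at the
  operating depths (≥ 10×) the 0.95/0.99 posterior threshold dominates
  the prior choice. Ties at the argmax resolve to canonical
  (lexicographic) order. Zero-depth sites return an undefined posterior
  and never pass.
* **Binomial.** Upper-tail `P(X ≥ k)` for the minor-allele count under
  `Binomial(n, e)`; the site is homozygous when the tail probability is
  ≥ α (default 0.05), i.e. the minor bases are explainable as error.
  `e` defaults to the mean per-base error of the site's DNA
  observations, floored at 1e-4; a constant override is accepted.
* **Frequency.** Alternative-allele fraction ≤ `max_alt_freq`
  (default 0, the strictest reading; configurable).

All three require DNA depth ≥ 10 to pass. The major allele is the modal
base, ties broken by reference base then lexicographically.

## Candidate detection and the cascade

Candidates are emitted wherever a non-redundant RNA read shows an
alternative base. Non-redundancy uses the footprint
`(start, end, strand, mate)` — the strictest reading of "overlapping
but not identical" — and both `k` (support) and `n` (depth) count
non-redundant reads, so PCR duplicates can neither create support nor
dilute the level.

The eleven cascade verdicts, all recorded per candidate so every
failure reason is reportable: homozygous DNA; no overlap with a
user-supplied SNP list; single editing type; support `k ≥ 3`; level
`k/n ≥ 0.05`; at least one supporting read with the site in its central
half (`floor(L/4)+1 … L − floor(L/4)`, fixed by the 90 bp → 23–68
example; computed per read from its own length); intronic sites more
than 6 bp from a splice boundary (exonic sites exempt); no reference
homopolymer run ≥ 5 containing the site; DNA depth ≤ 2× the genome-wide
mean (mean over covered positions by default; a depth-histogram peak
mode is available); the realignment test; and the FDR verdict. Filters
are pure predicates, so the outcome is independent of evaluation order.

**Sequencing-error test and FDR.** Support is tested against
`B(k, n, p)` with `p` the RNA error cap (`10^(−min_base_qual/10)`,
overridable). BH correction runs per sample over the candidates that
survived all non-statistical filters: correcting over already-rejected
sites would dilute the adjustment with hypotheses that are never
accepted anyway. Candidates rejected elsewhere carry no corrected
q-value; their FDR verdict records the raw p-value against the cutoff
(a lower bound on q), for reporting only.

**Strand and editing type.** For dUTP libraries the transcript strand
comes from read orientation (second-in-pair sense, single-end/first
antisense; invertible by configuration), by majority vote over
supporting reads. For unstranded libraries the strand of a uniquely
overlapping gene is used; otherwise the change is reported on the "+"
convention with strand ".". The type label is the reference→alternative
change complemented onto the transcript strand (genomic T→C in a minus
strand gene is reported A-to-G).

## Realignment filter

Supporting reads are realigned with an internal seed-and-extend local
aligner: exact 11-mers sampled every 4 cycles seed candidate loci,
each locus is rescored by banded edit-distance alignment of the read
against a padded genomic window (both orientations), and hits below
90 % identity are dropped. The hit score is matches-based — read length
minus edit distance — because the published contract is a score *ratio*
(second-best < 95 % of best) and a fraction rule (> 50 % of reads
qualifying, strict), both robust to the scorer's fine structure. An
optional adapter can ingest external PSL results instead. Spliced reads
are realigned as the aligned segment containing the candidate site
(spliced realignment is out of scope); segments shorter than the seed
are unevaluable and conservatively fail to qualify.

## Multiple samples

Editable positions are the union of fully passing sites across samples;
"unique region" and "splice distance" properties are inherited from the
discovery-time verdicts rather than re-evaluated. A position is removed
when any sample's DNA fails homozygosity there; samples whose DNA depth
is below the calling threshold do not veto, since shallow coverage is
not evidence of heterozygosity. Liberal retrieval then re-queries each
sample at these positions requiring only `k ≥ 1` and a BH-adjusted q
(computed per sample over exactly the queried set — the retrieval is a
targeted re-query, not a genome-wide scan) at or below the cutoff.
Merged output has one row per position with per-sample count blocks and
a status of discovered / retrieved / absent; retrieval never removes a
discovered site, and fixed (chrom, pos, strand) ordering makes repeated
runs byte-identical.

## Simulator

The generator emulates exactly the confounders the cascade targets:

* random 50-kb genome (default), 10 three-exon genes on both strands
  with CDS annotations; optional 500-bp copy of an edited exon window
  at configurable identity (97 % in the paralog study);
* heterozygous SNPs at 1 per kb with ploidy-valid allele counts, drawn
  in both DNA and RNA reads at genotype proportions;
* 50 editing sites on transcript-strand adenosines, levels uniform on
  [0.1, 0.9] by default (fixed and beta distributions available),
  placed outside homopolymer runs and ≥ 25 bp from transcript ends so
  mid-read support is attainable;
* 90-bp truth-aligned reads at 30× DNA / 50× RNA, per-base qualities
  N(35, 3) clipped to [2, 41] with errors at `10^(−q/10)`, 5 % PCR
  duplicates re-emitting a fragment with fresh errors, and dUTP
  orientation (paired mode available).

Problem sizes were chosen so a full simulate-plus-detect cycle runs in
seconds while every filter still has measurable work to do. What
passing tests show is that the statistical machinery and filter logic
behave as designed under these idealised conditions; the simulator does
not model mapping error (reads are truth-aligned), indels, expression
variation, chemistry-specific error profiles or hyper-edited reads, so
recall/precision on real libraries will also depend on the upstream
mapper and library quality.

## Numerical choices and degenerate inputs

Binomial tails come from `scipy.stats.binom.sf`; BH from
`statsmodels` (both cross-checked in the tests against exact
brute-force implementations). Posteriors are computed in log space and
normalised after subtracting the maximum. Empty observation lists give
log-likelihood 0 and a non-passing call; zero realigned reads fail the
realignment filter; an empty RNA layer yields an empty site table, not
an error. Boundary conventions: depth cap is inclusive (`depth ≤ 2 ×
mean` keeps), qualifying fraction is strict (`> 0.5`), the second-hit
rule is strict (`score₂ < 0.95·score₁` qualifies), splice distance
discards at `≤ 6`.

## Known limitations

Indels are neither simulated nor called; hyper-editing detection,
editing QTLs and differential editing are out of scope; the annotation
step reports the first frame-consistent transcript's codon change at
sites coding in several transcripts; repeat annotation requires a
user-supplied interval file. The whole genome is held in memory, which
is appropriate for the desk-scale and small-genome regimes the package
targets; chromosomes are processed independently, so larger genomes can
be partitioned externally.
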