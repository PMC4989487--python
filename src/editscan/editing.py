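"""Candidate editing-site detection, the filter cascade, and FDR control.

A site becomes a candidate when its RNA pileup shows a single
alternative base on at least one non-redundant read. The cascade then
requires, in reporting order: homozygous DNA, no known-SNP overlap, a
single editing type, >=3 non-redundant supporting reads, editing level
>=5 %, mid-read support, distance >6 bp from splice sites for intronic
sites, no homopolymer run >=5, DNA depth within 2x the genome mean,
survival of independent realignment (95 %/50 % rules), and a
Benjamini-Hochberg-corrected binomial sequencing-error test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional

from intervaltree import IntervalTree
from scipy.stats import binom
from statsmodels.stats.multitest import multipletests

from .models import (BASES, CASCADE_FILTERS, EditingCandidate, FilterConfig,
                     complement)

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Elementary predicates and statistics
# ---------------------------------------------------------------------------

def mid_read_window(read_len: int) -> tuple:
    """1-based first and last cycle of the central half of a read.

    For a 90-bp read this is positions 23..68.
    """
    if read_len < 4:
        raise ValueError("read length must be >= 4")
    q = read_len // 4
    return q + 1, read_len - q


def binom_error_test(k: int, n: int, p_err: float) -> float:
    """Upper-tail probability P(X >= k), X ~ Binomial(n, p_err).

    The null is that all k editing-supporting bases arose from
    sequencing error at rate ``p_err``.
    """
    if not 0 <= k <= n:
        raise ValueError("require 0 <= k <= n")
    if not 0.0 < p_err < 1.0:
        raise ValueError("p_err must be in (0, 1)")
    if k == 0:
        return 1.0
    return float(binom.sf(k - 1, n, p_err))


def bh_fdr(p_values) -> list:
    """Benjamini-Hochberg step-up adjusted q-values, in input order."""
    pvals = list(p_values)
    if not pvals:
        return []
    for p in pvals:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p-value {p} outside [0, 1]")
    return list(multipletests(pvals, method="fdr_bh")[1])


def homopolymer_filter(genome, chrom: str, pos: int,
                       homopolymer_len: int = 5) -> bool:
    """Keep (True) unless the reference run of identical bases containing
    ``pos`` is at least ``homopolymer_len`` long."""
    seq = genome.sequence(chrom)
    i = pos - 1
    b = seq[i]
    lo = i
    while lo > 0 and seq[lo - 1] == b:
        lo -= 1
    hi = i
    while hi + 1 < len(seq) and seq[hi + 1] == b:
        hi += 1
    return (hi - lo + 1) < homopolymer_len


def depth_cap_filter(dna_depth: int, genome_mean_depth: float,
                     factor: float = 2.0) -> bool:
    """Keep (True) unless DNA depth exceeds ``factor`` times the genome-wide
    depth (copy-number-variation guard)."""
    if genome_mean_depth <= 0:
        raise ValueError("genome mean depth must be positive")
    return dna_depth <= factor * genome_mean_depth


class SpliceIndex:
    """Exon/intron interval lookup for the splice-distance filter."""

    def __init__(self, transcripts: dict):
        self._exons: dict = {}
        self._introns: dict = {}
        for tr in transcripts.values():
            et = self._exons.setdefault(tr.chrom, IntervalTree())
            it = self._introns.setdefault(tr.chrom, IntervalTree())
            for s, e in tr.exons:
                et[s:e + 1] = (tr.transcript_id, tr.strand)
            for s, e in tr.introns():
                it[s:e + 1] = (tr.transcript_id, tr.strand)

    def is_exonic(self, chrom: str, pos: int) -> bool:
        t = self._exons.get(chrom)
        return bool(t and t[pos])

    def intron_distance(self, chrom: str, pos: int) -> Optional[int]:
        """Distance (bp, >=1) from an intronic position to the nearest splice
        boundary of a containing intron; None if not inside any intron."""
        t = self._introns.get(chrom)
        if not t:
            return None
        hits = t[pos]
        if not hits:
            return None
        dists = []
        for iv in hits:
            istart, iend = iv.begin, iv.end - 1
            dists.append(min(pos - istart + 1, iend - pos + 1))
        return min(dists)

    def gene_strands(self, chrom: str, pos: int) -> set:
        """Strands of genes (exons or introns) overlapping the position."""
        strands = set()
        for trees in (self._exons, self._introns):
            t = trees.get(chrom)
            if t:
                for iv in t[pos]:
                    strands.add(iv.data[1])
        return strands


def splice_distance_filter(chrom: str, pos: int, splice_index: SpliceIndex,
                           splice_dist: int = 6) -> bool:
    """Keep (True) unless the site is intronic and within ``splice_dist``
    bases of a splice site. Exonic sites are never discarded here."""
    if splice_index.is_exonic(chrom, pos):
        return True
    d = splice_index.intron_distance(chrom, pos)
    if d is None:  # intergenic
        return True
    return d > splice_dist


# ---------------------------------------------------------------------------
# Strand inference and candidate detection
# ---------------------------------------------------------------------------

def transcript_strand_of_read(read_strand: str, mate_flag: str,
                              invert: bool = False) -> str:
    """Transcript strand implied by a dUTP strand-specific read.

    Second-in-pair reads are sense to the transcript; single-end and
    first-in-pair reads are antisense. ``invert`` flips the rule for
    libraries with the opposite convention.
    """
    if mate_flag == "second":
        strand = read_strand
    else:
        strand = "-" if read_strand == "+" else "+"
    if invert:
        strand = "-" if strand == "+" else "+"
    return strand


def infer_edit_type(ref: str, alt: str, transcript_strand: str) -> tuple:
    """Express a genomic ref->alt mismatch on the transcript strand.

    Returns ``(ref_ts, alt_ts, label)`` where label is e.g. ``"A-to-G"``.
    For strand '.', the change is reported on the + convention.
    """
    if ref == alt:
        raise ValueError("ref and alt must differ")
    if transcript_strand == "-":
        ref, alt = complement(ref), complement(alt)
    return ref, alt, f"{ref}-to-{alt}"


def _nonredundant(obs: list) -> list:
    """One observation per mapping footprint (PCR-redundancy collapsing)."""
    best: dict = {}
    for o in obs:
        cur = best.get(o.footprint)
        if cur is None or (o.qual, o.read_id) > (cur.qual, cur.read_id):
            best[o.footprint] = o
    return sorted(best.values(), key=lambda o: (o.read_id, o.read_pos))


def detect_candidates(sites: Iterable, cfg: Optional[FilterConfig] = None,
                      library: str = "stranded_dUTP",
                      gene_strand_lookup: Optional[Callable] = None,
                      invert_strand_rule: bool = False) -> list:
    """Scan merged DNA/RNA site observations for candidate editing sites.

    ``sites`` iterates :class:`SiteObservations` whose RNA layer is already
    quality-filtered. A candidate is emitted wherever at least one
    non-redundant RNA read shows an alternative base; the ``multi_type``,
    ``support`` and ``level`` verdicts are recorded immediately, counting
    both k and n over non-redundant reads.
    """
    cfg = cfg or FilterConfig()
    out = []
    for site in sites:
        reps = _nonredundant(site.rna_obs)
        if not reps:
            continue
        counts = {b: 0 for b in BASES}
        for o in reps:
            if o.base in counts:
                counts[o.base] += 1
        alts = [b for b in BASES if b != site.ref_base and counts[b] > 0]
        if not alts:
            continue
        alt = max(alts, key=lambda b: (counts[b], b))
        n = sum(counts.values())
        k = counts[alt]
        level = k / n
        support_obs = [o for o in reps if o.base == alt]
        if library == "stranded_dUTP":
            votes = [transcript_strand_of_read(o.read_strand, o.mate_flag,
                                               invert_strand_rule)
                     for o in support_obs]
            plus = votes.count("+")
            minus = votes.count("-")
            strand = "+" if plus > minus else "-" if minus > plus else "."
        else:
            strands = gene_strand_lookup(site.chrom, site.pos) \
                if gene_strand_lookup else set()
            strand = next(iter(strands)) if len(strands) == 1 else "."
        ref_ts, alt_ts, label = infer_edit_type(
            site.ref_base, alt, strand if strand in "+-" else ".")
        cand = EditingCandidate(
            chrom=site.chrom, pos=site.pos, strand=strand,
            ref_base=ref_ts, edited_base=alt_ts, edit_type=label,
            n_total=n, k_edited=k, editing_level=level,
            supporting_obs=support_obs,
        )
        cand.filter_verdicts["multi_type"] = len(alts) == 1
        cand.filter_verdicts["support"] = k >= cfg.min_support_reads
        cand.filter_verdicts["level"] = level >= cfg.min_editing_level
        out.append(cand)
    return sorted(out, key=lambda c: (c.chrom, c.pos, c.strand))


# ---------------------------------------------------------------------------
# Cascade
# ---------------------------------------------------------------------------

@dataclass
class CascadeContext:
    """Everything the cascade needs beyond the candidate itself."""

    genome: object
    splice_index: SpliceIndex
    mean_dna_depth: float
    cfg: FilterConfig = field(default_factory=FilterConfig)
    known_snps: Optional[set] = None  # set of (chrom, pos); None = no list given
    realign_check: Optional[Callable] = None  # cand -> (fraction, bool)


def apply_filter_cascade(cand: EditingCandidate, ctx: CascadeContext) -> EditingCandidate:
    """Fill the candidate's full verdict map (FDR verdict finalized later).

    Every filter is a pure predicate of the candidate and context, so the
    outcome does not depend on evaluation order; all verdicts are always
    computed so failure reasons are fully reported.
    """
    cfg = ctx.cfg
    v = cand.filter_verdicts
    if cand.dna_call is None:
        raise ValueError("missing context element: genotype call (dna_call)")
    if ctx.genome is None:
        raise ValueError("missing context element: genome")
    if ctx.splice_index is None:
        raise ValueError("missing context element: splice_index")
    if ctx.realign_check is None:
        raise ValueError("missing context element: realign_check")
    v["dna_homozygous"] = bool(cand.dna_call.passes)
    v["known_snp_excluded"] = (ctx.known_snps is None
                               or (cand.chrom, cand.pos) not in ctx.known_snps)
    v.setdefault("multi_type", True)
    v["support"] = cand.k_edited >= cfg.min_support_reads
    v["level"] = cand.editing_level >= cfg.min_editing_level
    mid = False
    for o in cand.supporting_obs:
        first, last = mid_read_window(o.read_len)
        if first <= o.read_pos <= last:
            mid = True
            break
    v["mid_read"] = mid
    v["splice_distance"] = splice_distance_filter(
        cand.chrom, cand.pos, ctx.splice_index, cfg.splice_dist)
    v["homopolymer"] = homopolymer_filter(
        ctx.genome, cand.chrom, cand.pos, cfg.homopolymer_len)
    v["depth_cap"] = depth_cap_filter(
        cand.dna_call.dna_depth, ctx.mean_dna_depth, cfg.depth_cap_factor)
    frac_pass = ctx.realign_check(cand)
    if isinstance(frac_pass, tuple):
        _, realign_ok = frac_pass
    else:
        realign_ok = bool(frac_pass)
    v["realign_qualified"] = realign_ok
    cand.p_value = binom_error_test(cand.k_edited, cand.n_total, cfg.err_upper)
    # ordered map for reporting
    cand.filter_verdicts = {name: v[name] for name in CASCADE_FILTERS
                            if name in v}
    return cand


def finalize_fdr(cands: list, cfg: Optional[FilterConfig] = None) -> list:
    """BH-correct the binomial p-values and set the ``fdr_pass`` verdict.

    The correction runs over candidates that survived every non-statistical
    filter. Candidates already rejected elsewhere carry no corrected
    q-value; their ``fdr_pass`` records whether the raw p-value clears the
    cutoff (a lower bound on q, reported for completeness).
    """
    cfg = cfg or FilterConfig()
    pre = [name for name in CASCADE_FILTERS if name != "fdr_pass"]
    in_fdr = [c for c in cands
              if all(c.filter_verdicts.get(name, True) for name in pre)]
    qvals = bh_fdr([c.p_value for c in in_fdr])
    for c, q in zip(in_fdr, qvals):
        c.q_value = float(q)
        c.filter_verdicts["fdr_pass"] = bool(q <= cfg.fdr_cutoff)
    in_set = set(map(id, in_fdr))
    for c in cands:
        if id(c) not in in_set:
            c.q_value = None
            c.filter_verdicts["fdr_pass"] = (c.p_value is not None
                                             and c.p_value <= cfg.fdr_cutoff)
    return cands
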