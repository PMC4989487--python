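"""Alignment input, read filtering, splice-junction lift-over and pileups.

This module turns coordinate-sorted SAM/BAM alignments plus a reference
FASTA and gene models into per-site stacks of base observations
(:class:`~editscan.models.SiteObservations`), applying the read-level
hygiene the downstream statistics assume: unique alignments only, PCR
duplicates collapsed, read ends clipped, junction-mapped reads lifted
back to genomic coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pysam

from .models import BaseObservation, JunctionRecord, ReadAlignment, SiteObservations

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Genome access
# ---------------------------------------------------------------------------

class Genome:
    """Uniform access to a reference genome from a FASTA path or a dict."""

    def __init__(self, source):
        if isinstance(source, Genome):
            self._seqs = source._seqs
        elif isinstance(source, dict):
            self._seqs = {k: str(v).upper() for k, v in source.items()}
        else:
            import pyfaidx

            fa = pyfaidx.Fasta(str(source))
            self._seqs = {name: str(fa[name][:]).upper() for name in fa.keys()}

    def __contains__(self, chrom) -> bool:
        return chrom in self._seqs

    def chroms(self):
        return list(self._seqs)

    def length(self, chrom: str) -> int:
        return len(self._seqs[chrom])

    def sequence(self, chrom: str) -> str:
        if chrom not in self._seqs:
            raise KeyError(f"chromosome {chrom!r} absent from genome")
        return self._seqs[chrom]

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """1-based inclusive slice, clipped to the contig."""
        seq = self.sequence(chrom)
        return seq[max(start - 1, 0):min(end, len(seq))]

    def base(self, chrom: str, pos: int) -> str:
        return self.sequence(chrom)[pos - 1]


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

@dataclass
class Transcript:
    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list = field(default_factory=list)  # [(start, end)] 1-based, sorted
    cds: list = field(default_factory=list)  # [(start, end)] 1-based, sorted

    def introns(self):
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 > e1 + 1:
                out.append((e1 + 1, s2 - 1))
        return out

    @property
    def span(self):
        return self.exons[0][0], self.exons[-1][1]


def load_gene_models(path) -> dict:
    """Parse exon/CDS chains from a GTF or GFF3 file into Transcript records."""
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    transcripts: dict = {}
    for ftype in ("exon", "CDS"):
        for feat in db.features_of_type(ftype):
            if "transcript_id" in feat.attributes:
                tids = feat.attributes["transcript_id"]
            elif "Parent" in feat.attributes:
                tids = feat.attributes["Parent"]
            else:  # pragma: no cover - malformed row
                log.warning("feature without transcript_id/Parent skipped: %s", feat)
                continue
            gene = feat.attributes.get("gene_id", [""])[0] or feat.attributes.get(
                "gene", [""])[0]
            for tid in tids:
                tr = transcripts.setdefault(
                    tid, Transcript(tid, gene, feat.seqid, feat.strand))
                if ftype == "exon":
                    tr.exons.append((feat.start, feat.end))
                else:
                    tr.cds.append((feat.start, feat.end))
    for tr in transcripts.values():
        tr.exons = sorted(set(tr.exons))
        tr.cds = sorted(set(tr.cds))
    return transcripts


# ---------------------------------------------------------------------------
# Junction library
# ---------------------------------------------------------------------------

def build_junction_library(genome, transcripts: dict, read_length: int):
    """Build junction contigs of exonic sequence flanking every splice junction.

    Each junction yields one contig composed of the last ``read_length - 1``
    exonic bases upstream of the junction and the first ``read_length - 1``
    downstream, so that a read can hit either the genome or the junction
    contig but never both. Flanks are truncated at exon/contig boundaries
    and flagged. Returns ``(contigs, records)`` where ``contigs`` is a list
    of ``(junction_id, sequence)``.

    >>> # read_length=90 gives 89 bp per side
    """
    if read_length < 2:
        raise ValueError("read_length must be >= 2")
    genome = genome if isinstance(genome, Genome) else Genome(genome)
    flank = read_length - 1
    seen = {}
    records = []
    contigs = []
    for tid in sorted(transcripts):
        tr = transcripts[tid]
        exons = tr.exons
        for (ls, le), (rs, re) in zip(exons, exons[1:]):
            if rs <= le:
                continue
            key = (tr.chrom, le, rs)
            if key in seen:
                continue
            if tr.chrom not in genome:
                log.warning("junction on unknown chromosome %s skipped", tr.chrom)
                continue
            clen = genome.length(tr.chrom)
            if le < 1 or rs > clen:
                log.warning("junction %s:%d-%d outside genome bounds, skipped",
                            tr.chrom, le, rs)
                continue
            left_flank = min(flank, le - ls + 1, le)
            right_flank = min(flank, re - rs + 1, clen - rs + 1)
            jid = f"junc_{tr.chrom}_{le}_{rs}"
            rec = JunctionRecord(
                junction_id=jid, chrom=tr.chrom, left_exon_end=le,
                right_exon_start=rs, flank_length=flank, strand=tr.strand,
                left_flank=left_flank, right_flank=right_flank,
                truncated=(left_flank < flank or right_flank < flank),
            )
            seq = (genome.fetch(tr.chrom, le - left_flank + 1, le)
                   + genome.fetch(tr.chrom, rs, rs + right_flank - 1))
            seen[key] = rec
            records.append(rec)
            contigs.append((jid, seq))
    return contigs, records


def write_junction_library(contigs, records, prefix) -> None:
    """Write the junction library as ``<prefix>.fa`` and ``<prefix>.tsv``."""
    with open(f"{prefix}.fa", "w") as fh:
        for jid, seq in contigs:
            fh.write(f">{jid}\n{seq}\n")
    with open(f"{prefix}.tsv", "w") as fh:
        fh.write("junction_id\tchrom\tleft_exon_end\tright_exon_start"
                 "\tflank_length\tstrand\n")
        for rec in records:
            fh.write(f"{rec.junction_id}\t{rec.chrom}\t{rec.left_exon_end}"
                     f"\t{rec.right_exon_start}\t{rec.flank_length}\t{rec.strand}\n")


def lift_offset(jrec: JunctionRecord, offset: int) -> int:
    """Map a 1-based junction-contig offset to its genomic position."""
    if offset < 1 or offset > jrec.left_flank + jrec.right_flank:
        raise ValueError("offset outside junction contig")
    if offset <= jrec.left_flank:
        return jrec.left_exon_end - (jrec.left_flank - offset)
    return jrec.right_exon_start + (offset - jrec.left_flank - 1)


def project_offset(jrec: JunctionRecord, gpos: int) -> int:
    """Inverse of :func:`lift_offset` (genomic position -> contig offset)."""
    left_start = jrec.left_exon_end - jrec.left_flank + 1
    if left_start <= gpos <= jrec.left_exon_end:
        return jrec.left_flank - (jrec.left_exon_end - gpos)
    right_end = jrec.right_exon_start + jrec.right_flank - 1
    if jrec.right_exon_start <= gpos <= right_end:
        return jrec.left_flank + (gpos - jrec.right_exon_start) + 1
    raise ValueError("genomic position not covered by junction flanks")


def lift_junction_alignment(aln: ReadAlignment, jrec: JunctionRecord) -> ReadAlignment:
    """Convert a junction-contig alignment to a split genomic alignment.

    The alignment must span the junction midpoint; alignments confined to
    one flank duplicate the genomic hit and are rejected.
    """
    if aln.source != "junction":
        raise ValueError("alignment does not come from the junction library")
    if not (aln.start <= jrec.left_flank and aln.end >= jrec.left_flank + 1):
        raise ValueError("junction alignment does not span the junction")
    gap = jrec.right_exon_start - jrec.left_exon_end - 1
    new_cigar = []
    rpos = aln.start  # contig coordinate of next reference-consuming base
    crossed = rpos > jrec.left_flank
    for op, ln in aln.cigar:
        if op in "M=XDN":
            while ln > 0:
                if not crossed and rpos + ln - 1 > jrec.left_flank:
                    take = jrec.left_flank - rpos + 1
                    new_cigar.append((op, take))
                    new_cigar.append(("N", gap))
                    crossed = True
                    rpos += take
                    ln -= take
                else:
                    new_cigar.append((op, ln))
                    rpos += ln
                    ln = 0
        else:
            new_cigar.append((op, ln))
    # merge adjacent same-op runs produced by the split
    merged = []
    for op, ln in new_cigar:
        if merged and merged[-1][0] == op:
            merged[-1] = (op, merged[-1][1] + ln)
        else:
            merged.append((op, ln))
    return ReadAlignment(
        read_id=aln.read_id, chrom=jrec.chrom,
        start=lift_offset(jrec, aln.start), strand=aln.strand,
        mate_flag=aln.mate_flag, mapq=aln.mapq, cigar=merged,
        bases=aln.bases, quals=aln.quals, tags=dict(aln.tags),
        source="junction", clip_mask=aln.clip_mask,
    )


# ---------------------------------------------------------------------------
# SAM/BAM reading and read-level filtering
# ---------------------------------------------------------------------------

_CIGAR_OPS = "MIDNSHP=X"


def read_alignments(path, source: str = "genome") -> list:
    """Read mapped, primary alignments from SAM/BAM into ReadAlignment records."""
    out = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for rec in fh:
            if (rec.is_unmapped or rec.is_secondary or rec.is_supplementary
                    or rec.query_sequence is None):
                continue
            if rec.is_paired:
                mate_flag = "first" if rec.is_read1 else "second"
            else:
                mate_flag = "single"
            cigar = [(_CIGAR_OPS[op], ln) for op, ln in rec.cigartuples]
            quals = list(rec.query_qualities) if rec.query_qualities is not None \
                else [30] * len(rec.query_sequence)
            out.append(ReadAlignment(
                read_id=rec.query_name,
                chrom=rec.reference_name,
                start=rec.reference_start + 1,
                strand="-" if rec.is_reverse else "+",
                mate_flag=mate_flag,
                mapq=rec.mapping_quality,
                cigar=cigar,
                bases=rec.query_sequence.upper(),
                quals=quals,
                tags=dict(rec.get_tags()),
                source=source,
                mate_chrom=rec.next_reference_name if rec.is_paired else None,
                mate_pos=(rec.next_reference_start + 1) if rec.is_paired else None,
            ))
    return out


@dataclass
class ReadFilterPolicy:
    """Read retention rules: uniqueness, duplicate collapsing, end clipping."""

    clip_n: int = 6
    mapq_floor: int = 20
    check_sorted: bool = True


def _is_unique(aln: ReadAlignment, policy: ReadFilterPolicy, warned: list) -> bool:
    tags = aln.tags
    if "X0" in tags:  # BWA: number of best hits / suboptimal hits
        return tags.get("X0", 0) == 1 and tags.get("X1", 0) == 0
    if "NH" in tags:
        return tags["NH"] == 1
    if not warned:
        log.info("no uniqueness tags found; falling back to MAPQ >= %d",
                 policy.mapq_floor)
        warned.append(True)
    return aln.mapq >= policy.mapq_floor


def _dup_key(aln: ReadAlignment):
    if aln.mate_flag == "single":
        return (aln.chrom, aln.start, aln.end, aln.strand, "single")
    return (aln.chrom, aln.start, aln.strand, aln.mate_chrom, aln.mate_pos,
            aln.mate_flag)


def filter_reads(alns: Iterable[ReadAlignment],
                 policy: Optional[ReadFilterPolicy] = None) -> list:
    """Keep uniquely aligned reads, collapse PCR duplicates, mark end clips.

    Duplicate groups share an identical mapping footprint (for pairs, the
    pair coordinates); the member with the highest mapping quality is kept,
    ties broken by read id so the result is order-independent.
    """
    policy = policy or ReadFilterPolicy()
    warned: list = []
    best: dict = {}
    last_start: dict = {}
    for aln in alns:
        if policy.check_sorted:
            prev = last_start.get(aln.chrom)
            if prev is not None and aln.start < prev:
                raise ValueError(
                    f"input not coordinate-sorted at {aln.chrom}:{aln.start}")
            last_start[aln.chrom] = aln.start
        if not _is_unique(aln, policy, warned):
            continue
        key = _dup_key(aln)
        cur = best.get(key)
        if cur is None or (aln.mapq, aln.read_id) > (cur.mapq, cur.read_id):
            best[key] = aln
    kept = sorted(best.values(),
                  key=lambda a: (a.chrom, a.start, a.end, a.read_id, a.mate_flag))
    for aln in kept:
        aln.clip_mask = policy.clip_n
    return kept


# ---------------------------------------------------------------------------
# Pileup
# ---------------------------------------------------------------------------

def pileup(alns: Iterable[ReadAlignment], genome, layer: str = "dna",
           min_base_qual: int = 0, region: Optional[tuple] = None,
           positions: Optional[set] = None) -> dict:
    """Stack per-site base observations from filtered reads.

    Bases that are ``N``, below ``min_base_qual``, or inside the masked
    (clipped) read ends contribute nothing. Returns a dict mapping
    ``(chrom, pos)`` to :class:`SiteObservations` with the requested layer
    (``'dna'`` or ``'rna'``) populated.
    """
    genome = genome if isinstance(genome, Genome) else Genome(genome)
    sites: dict = {}
    for aln in alns:
        if aln.chrom not in genome:
            raise KeyError(f"chromosome {aln.chrom!r} absent from genome")
        if region is not None:
            rchrom, rstart, rend = region
            if aln.chrom != rchrom or aln.end < rstart or aln.start > rend:
                continue
        lo = aln.clip_mask
        hi = aln.read_len - aln.clip_mask
        rstart, rend = aln.start, aln.end
        for qpos, rpos in aln.aligned_pairs():
            if qpos <= lo or qpos > hi:
                continue
            if region is not None and not (region[1] <= rpos <= region[2]):
                continue
            if positions is not None and (aln.chrom, rpos) not in positions:
                continue
            base = aln.bases[qpos - 1]
            qual = aln.quals[qpos - 1]
            if base == "N" or qual < min_base_qual:
                continue
            key = (aln.chrom, rpos)
            site = sites.get(key)
            if site is None:
                site = SiteObservations(
                    chrom=aln.chrom, pos=rpos,
                    ref_base=genome.base(aln.chrom, rpos))
                sites[key] = site
            obs = BaseObservation(
                base=base, qual=qual, read_id=aln.read_id, read_pos=qpos,
                read_len=aln.read_len, read_start=rstart, read_end=rend,
                read_strand=aln.strand, mate_flag=aln.mate_flag)
            (site.dna_obs if layer == "dna" else site.rna_obs).append(obs)
    return sites


def mean_coverage(alns: Iterable[ReadAlignment], genome) -> float:
    """Mean aligned depth over positions covered by at least one read."""
    genome = genome if isinstance(genome, Genome) else Genome(genome)
    diffs: dict = {}
    for aln in alns:
        arr = diffs.get(aln.chrom)
        if arr is None:
            arr = diffs[aln.chrom] = np.zeros(genome.length(aln.chrom) + 2,
                                              dtype=np.int64)
        for _, _, rs, re in aln.aligned_blocks():
            arr[rs] += 1
            arr[re + 1] -= 1
    total = covered = 0
    for arr in diffs.values():
        depth = np.cumsum(arr)[1:-1]
        mask = depth > 0
        covered += int(mask.sum())
        total += int(depth[mask].sum())
    return total / covered if covered else 0.0


def depth_histogram_peak(alns: Iterable[ReadAlignment], genome) -> int:
    """Modal depth over covered positions (the 'peak' of the depth histogram)."""
    genome = genome if isinstance(genome, Genome) else Genome(genome)
    counts: dict = {}
    diffs: dict = {}
    for aln in alns:
        arr = diffs.get(aln.chrom)
        if arr is None:
            arr = diffs[aln.chrom] = np.zeros(genome.length(aln.chrom) + 2,
                                              dtype=np.int64)
        for _, _, rs, re in aln.aligned_blocks():
            arr[rs] += 1
            arr[re + 1] -= 1
    for arr in diffs.values():
        depth = np.cumsum(arr)[1:-1]
        for d in depth[depth > 0]:
            counts[int(d)] = counts.get(int(d), 0) + 1
    if not counts:
        return 0
    return max(sorted(counts), key=lambda d: counts[d])
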