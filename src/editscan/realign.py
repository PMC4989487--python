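"""Independent realignment of editing-supporting reads (paralog guard).

Reads that support editing are realigned against the genome with a
seed-and-extend local aligner that is independent of the original
mapper: exact k-mer seeds locate candidate loci, and each locus is
rescored by banded edit-distance alignment (edlib) of the read against
the genomic window. The hit score is matches-based (read length minus
edit distance). A read *qualifies* when its best hit overlaps the
original candidate site and any second-best hit scores below 95 % of
the best; a candidate survives only when qualifying reads exceed 50 %
of all realigned reads.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import edlib

from .models import revcomp


@dataclass
class RealignHit:
    read_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    strand: str
    score: float
    rank: int = 0


class Realigner:
    """Seed-and-extend local aligner over a (small) reference genome."""

    def __init__(self, genome, seed_len: int = 11, min_identity: float = 0.90,
                 seed_step: int = 4, max_loci_per_seed: int = 50):
        from .alignio import Genome

        self.genome = genome if isinstance(genome, Genome) else Genome(genome)
        self.seed_len = seed_len
        self.min_identity = min_identity
        self.seed_step = seed_step
        self.max_loci_per_seed = max_loci_per_seed
        self._index: dict = {}
        k = seed_len
        for chrom in self.genome.chroms():
            seq = self.genome.sequence(chrom)
            for i in range(0, len(seq) - k + 1):
                kmer = seq[i:i + k]
                if "N" in kmer:
                    continue
                self._index.setdefault(kmer, []).append((chrom, i + 1))

    def _candidate_loci(self, seq: str):
        """Cluster seed hits by approximate diagonal -> (chrom, diag) set."""
        k = self.seed_len
        loci = set()
        for off in range(0, max(len(seq) - k + 1, 1), self.seed_step):
            hits = self._index.get(seq[off:off + k])
            if not hits or len(hits) > self.max_loci_per_seed:
                continue
            for chrom, pos in hits:
                diag = pos - off  # genomic position read base 1 would take
                loci.add((chrom, diag))
        # merge nearby diagonals (indel tolerance)
        merged: dict = {}
        for chrom, diag in sorted(loci):
            key = (chrom, diag // 8)
            if key not in merged:
                merged[key] = (chrom, diag)
        return list(merged.values())

    def align(self, read_id: str, seq: str) -> list:
        """All local hits of ``seq`` (both orientations), ranked by score."""
        hits = []
        for strand, s in (("+", seq), ("-", revcomp(seq))):
            for chrom, diag in self._candidate_loci(s):
                pad = max(len(s) // 5, 8)
                wstart = max(diag - pad, 1)
                wend = min(diag + len(s) - 1 + pad, self.genome.length(chrom))
                window = self.genome.fetch(chrom, wstart, wend)
                max_d = int(len(s) * (1.0 - self.min_identity)) + 1
                res = edlib.align(s, window, mode="HW", task="locations", k=max_d)
                if res["editDistance"] < 0:
                    continue
                d = res["editDistance"]
                if (len(s) - d) / len(s) < self.min_identity:
                    continue
                loc = res["locations"][0]
                hstart = wstart + loc[0]
                hend = wstart + loc[1]
                hits.append(RealignHit(
                    read_id=read_id, chrom=chrom, start=hstart, end=hend,
                    strand=strand, score=float(len(s) - d)))
        # collapse hits covering the same locus, keep the best per locus
        best: dict = {}
        for h in hits:
            key = (h.chrom, h.start // 20)
            cur = best.get(key)
            if cur is None or h.score > cur.score:
                best[key] = h
        ranked = sorted(best.values(),
                        key=lambda h: (-h.score, h.chrom, h.start, h.strand))
        for i, h in enumerate(ranked, 1):
            h.rank = i
        return ranked


def realign_supporting_reads(reads: Iterable, realigner: Realigner) -> dict:
    """Realign each supporting read segment; reads with no usable sequence
    map to None (the candidate then fails the filter conservatively).

    ``reads`` iterates ``(read_id, sequence)`` pairs, where sequence is the
    aligned read segment containing the candidate site.
    """
    out: dict = {}
    for read_id, seq in reads:
        if not seq or len(seq) < realigner.seed_len:
            out[read_id] = None
            continue
        out[read_id] = realigner.align(read_id, seq)
    return out


def qualifying_fraction(cand_chrom: str, cand_pos: int, realignments: dict,
                        second_ratio: float = 0.95,
                        min_fraction: float = 0.50) -> tuple:
    """Fraction of qualifying realigned reads and the strict >50 % verdict.

    Qualifying: the best hit's span contains the candidate position and any
    second-best hit scores strictly below ``second_ratio`` times the best.
    Zero realigned reads fail.
    """
    n = 0
    q = 0
    for hits in realignments.values():
        n += 1
        if not hits:
            continue  # unevaluable or no hit -> not qualifying
        best = hits[0]
        if not (best.chrom == cand_chrom and best.start <= cand_pos <= best.end):
            continue
        if len(hits) > 1 and hits[1].score >= second_ratio * best.score:
            continue
        q += 1
    if n == 0:
        return 0.0, False
    frac = q / n
    return frac, frac > min_fraction
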