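"""Genomic-feature annotation and codon/amino-acid consequences.

Passing sites are labelled with every overlapping feature class (exon,
intron, CDS, 5'-UTR, 3'-UTR, repeat; intergenic when none), and sites
inside a CDS get the codon and amino-acid change implied by the edit,
computed on the coding strand honouring splicing and frame.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

from Bio.Seq import Seq
from intervaltree import IntervalTree

from .models import complement

log = logging.getLogger(__name__)

FEATURE_CLASSES = ("CDS", "5'-UTR", "3'-UTR", "exon", "intron", "repeat")


@dataclass
class CodonChange:
    codon_before: str
    codon_after: str
    aa_before: str
    aa_after: str
    synonymous: bool
    codon_position: int  # 1..3 within the codon
    transcript_id: str = ""


class FeatureIndex:
    """Per-chromosome interval lookup over annotated feature classes.

    Built from transcript models (exons/CDS; introns and UTRs derived)
    plus optional repeat intervals. Lookup order and input order do not
    affect results.
    """

    def __init__(self, transcripts: Optional[dict] = None,
                 repeats: Optional[list] = None):
        self._trees: dict = {}
        if transcripts:
            for tid in sorted(transcripts):
                tr = transcripts[tid]
                for s, e in tr.exons:
                    self._add(tr.chrom, s, e, "exon", tr)
                for s, e in tr.introns():
                    self._add(tr.chrom, s, e, "intron", tr)
                for s, e in tr.cds:
                    self._add(tr.chrom, s, e, "CDS", tr)
                self._add_utrs(tr)
        for chrom, s, e in repeats or []:
            self._add(chrom, s, e, "repeat", None)

    def _add(self, chrom, start, end, klass, tr):
        if end < start:
            log.warning("malformed feature row %s:%d-%d skipped", chrom, start, end)
            return
        tree = self._trees.setdefault(chrom, IntervalTree())
        tree[start:end + 1] = (klass,
                               tr.gene_id if tr else "",
                               tr.transcript_id if tr else "")

    def _add_utrs(self, tr):
        if not tr.cds:
            return
        cds_lo = min(s for s, _ in tr.cds)
        cds_hi = max(e for _, e in tr.cds)
        for s, e in tr.exons:
            left = (s, min(e, cds_lo - 1))
            right = (max(s, cds_hi + 1), e)
            for us, ue in (left, right):
                if ue < us:
                    continue
                if ue < cds_lo:
                    klass = "5'-UTR" if tr.strand == "+" else "3'-UTR"
                elif us > cds_hi:
                    klass = "3'-UTR" if tr.strand == "+" else "5'-UTR"
                else:
                    continue
                self._add(tr.chrom, us, ue, klass, tr)

    def annotate_site(self, chrom: str, pos: int) -> list:
        """Sorted feature-class labels overlapping the site; ['intergenic']
        when nothing overlaps."""
        tree = self._trees.get(chrom)
        classes = sorted({iv.data[0] for iv in tree[pos]}) if tree else []
        return classes or ["intergenic"]

    def genes_at(self, chrom: str, pos: int) -> list:
        tree = self._trees.get(chrom)
        if not tree:
            return []
        return sorted({iv.data[1] for iv in tree[pos] if iv.data[1]})


def spliced_cds(transcript, genome) -> tuple:
    """Assemble the coding sequence and its genomic coordinate map.

    Returns ``(seq, coords)`` where ``seq`` is the CDS on the coding strand
    and ``coords[i]`` is the genomic position of base ``i``. Minus-strand
    transcripts are reverse-complemented.
    """
    parts = []
    coords = []
    for s, e in sorted(transcript.cds):
        parts.append(genome.fetch(transcript.chrom, s, e))
        coords.extend(range(s, e + 1))
    seq = "".join(parts)
    if transcript.strand == "-":
        seq = str(Seq(seq).reverse_complement())
        coords = coords[::-1]
    return seq, coords


def codon_change(chrom: str, pos: int, edited_base_plus: str, transcript,
                 genome) -> Optional[CodonChange]:
    """Codon and amino-acid change implied by editing a CDS position.

    ``edited_base_plus`` is the edited base expressed on the genomic +
    strand; it is complemented onto the coding strand for minus-strand
    transcripts. Returns None (with a warning) when the assembled CDS is
    frame-inconsistent or the position is not coding in this transcript.
    """
    seq, coords = spliced_cds(transcript, genome)
    if not seq or len(seq) % 3 != 0:
        log.warning("CDS of %s is frame-inconsistent (len %d); "
                    "no codon change computed", transcript.transcript_id, len(seq))
        return None
    try:
        idx = coords.index(pos)
    except ValueError:
        return None
    new_base = edited_base_plus if transcript.strand == "+" \
        else complement(edited_base_plus)
    ci = idx // 3
    cp = idx % 3
    before = seq[ci * 3:ci * 3 + 3]
    after = before[:cp] + new_base + before[cp + 1:]
    aa_before = str(Seq(before).translate())
    aa_after = str(Seq(after).translate())
    return CodonChange(
        codon_before=before, codon_after=after,
        aa_before=aa_before, aa_after=aa_after,
        synonymous=(aa_before == aa_after), codon_position=cp + 1,
        transcript_id=transcript.transcript_id)


def read_repeat_bed(path, dialect: str = "bed") -> list:
    """Read repeat intervals from BED (0-based half-open) or 1-based TSV."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                log.warning("malformed repeat row skipped: %r", line)
                continue
            chrom, a, b = parts[0], int(parts[1]), int(parts[2])
            if dialect == "bed":
                out.append((chrom, a + 1, b))
            else:
                out.append((chrom, a, b))
    return out


def annotate_candidate(cand, feature_index: FeatureIndex, transcripts: dict,
                       genome) -> dict:
    """Full annotation block for one candidate: feature classes, gene ids,
    and the codon change from the first CDS transcript containing it."""
    classes = feature_index.annotate_site(cand.chrom, cand.pos)
    genes = feature_index.genes_at(cand.chrom, cand.pos)
    change = None
    if "CDS" in classes:
        # edited base expressed on the genomic + strand
        edited_plus = cand.edited_base if cand.strand != "-" \
            else complement(cand.edited_base)
        for tid in sorted(transcripts):
            tr = transcripts[tid]
            if tr.chrom != cand.chrom or not tr.cds:
                continue
            if any(s <= cand.pos <= e for s, e in tr.cds):
                change = codon_change(cand.chrom, cand.pos, edited_plus, tr, genome)
                if change is not None:
                    break
    return {
        "feature_classes": ",".join(classes),
        "gene_id": ",".join(genes),
        "codon_before": change.codon_before if change else "",
        "codon_after": change.codon_after if change else "",
        "aa_before": change.aa_before if change else "",
        "aa_after": change.aa_after if change else "",
        "synonymous": ("yes" if change.synonymous else "no") if change else "",
    }
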