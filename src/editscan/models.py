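"""Core domain types shared by all pipeline stages.

All genomic coordinates in these records are 1-based inclusive (SAM
convention). Read-level coordinates (``read_pos``) are 1-based offsets
within the read as stored, counting from the first base of the record.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

BASES = ("A", "C", "G", "T")

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def complement(base: str) -> str:
    return base.translate(_COMP)


@dataclass(frozen=True)
class BaseObservation:
    """One base call at one genomic site, with its read context."""

    base: str
    qual: int
    read_id: str
    read_pos: int  # 1-based cycle within the read
    read_len: int
    read_start: int  # genomic span of the source read
    read_end: int
    read_strand: str  # '+' or '-'
    mate_flag: str  # 'single', 'first', 'second'

    @property
    def error_prob(self) -> float:
        return 10.0 ** (-self.qual / 10.0)

    @property
    def footprint(self) -> tuple:
        """Mapping footprint used for PCR-redundancy collapsing."""
        return (self.read_start, self.read_end, self.read_strand, self.mate_flag)


@dataclass
class SiteObservations:
    """Stacked DNA and RNA base calls at a single genomic position."""

    chrom: str
    pos: int
    ref_base: str
    dna_obs: list = field(default_factory=list)
    rna_obs: list = field(default_factory=list)

    @property
    def dna_depth(self) -> int:
        return len(self.dna_obs)

    @property
    def rna_depth(self) -> int:
        return len(self.rna_obs)


@dataclass(frozen=True)
class Genotype:
    """A multiset of alleles of cardinality equal to the sample ploidy."""

    alleles: tuple  # sorted tuple of bases, length == ploidy

    def __post_init__(self):
        object.__setattr__(self, "alleles", tuple(sorted(self.alleles)))

    @property
    def ploidy(self) -> int:
        return len(self.alleles)

    @property
    def distinct_count(self) -> int:
        return len(set(self.alleles))

    @property
    def is_homozygous(self) -> bool:
        return self.distinct_count == 1

    def allele_fractions(self) -> dict:
        p = self.ploidy
        out: dict = {}
        for a in self.alleles:
            out[a] = out.get(a, 0.0) + 1.0 / p
        return out

    def __str__(self) -> str:
        return "".join(self.alleles)


@dataclass
class GenotypeCall:
    """Verdict on whether a site's DNA supports a reliable homozygous genotype."""

    chrom: str
    pos: int
    model: str  # 'bayes', 'binomial' or 'frequency'
    best_genotype: Optional[Genotype]
    posterior: Optional[float]  # posterior prob (bayes) or p-value/score (others)
    dna_depth: int
    is_homozygous: bool
    passes: bool


@dataclass(frozen=True)
class JunctionRecord:
    """One splice junction and the geometry of its library contig.

    ``left_flank``/``right_flank`` are the realised flank lengths, which
    may be shorter than ``flank_length`` when truncated at contig or exon
    boundaries (then ``truncated`` is set).
    """

    junction_id: str
    chrom: str
    left_exon_end: int
    right_exon_start: int
    flank_length: int
    strand: str
    left_flank: int = -1
    right_flank: int = -1
    truncated: bool = False

    def __post_init__(self):
        if self.left_flank < 0:
            object.__setattr__(self, "left_flank", self.flank_length)
        if self.right_flank < 0:
            object.__setattr__(self, "right_flank", self.flank_length)


@dataclass
class ReadAlignment:
    """A single aligned read (or lifted junction alignment)."""

    read_id: str
    chrom: str
    start: int  # 1-based inclusive leftmost aligned reference base
    strand: str
    mate_flag: str
    mapq: int
    cigar: list  # list of (op, length); ops from MIDNSHP=X
    bases: str
    quals: list
    tags: dict = field(default_factory=dict)
    source: str = "genome"  # 'genome' or 'junction'
    mate_chrom: Optional[str] = None
    mate_pos: Optional[int] = None
    clip_mask: int = 0  # cycles masked at each end at pileup time

    @property
    def end(self) -> int:
        """1-based inclusive rightmost aligned reference base."""
        span = 0
        for op, ln in self.cigar:
            if op in "MDN=X":
                span += ln
        return self.start + span - 1

    @property
    def read_len(self) -> int:
        return len(self.bases)

    def aligned_pairs(self):
        """Yield (read_pos, ref_pos), both 1-based, for aligned (M/=/X) cycles."""
        qpos = 0
        rpos = self.start
        for op, ln in self.cigar:
            if op in "M=X":
                for i in range(ln):
                    yield qpos + i + 1, rpos + i
                qpos += ln
                rpos += ln
            elif op in "IS":
                qpos += ln
            elif op in "DN":
                rpos += ln
            # H and P consume nothing we track

    def aligned_blocks(self):
        """Contiguous aligned blocks as (read_start, read_end, ref_start, ref_end),
        all 1-based inclusive. A block breaks at I/D/N/S operations."""
        blocks = []
        qpos = 0
        rpos = self.start
        for op, ln in self.cigar:
            if op in "M=X":
                blocks.append((qpos + 1, qpos + ln, rpos, rpos + ln - 1))
                qpos += ln
                rpos += ln
            elif op in "IS":
                qpos += ln
            elif op in "DN":
                rpos += ln
        return blocks


@dataclass
class EditingCandidate:
    """A candidate RNA-editing site with counts and per-filter verdicts."""

    chrom: str
    pos: int
    strand: str  # transcript strand: '+', '-' or '.'
    ref_base: str  # on the reported strand
    edited_base: str  # on the reported strand
    edit_type: str  # e.g. 'A-to-G'
    n_total: int  # non-redundant RNA reads covering the site
    k_edited: int  # non-redundant RNA reads supporting editing
    editing_level: float
    dna_call: Optional[GenotypeCall] = None
    supporting_obs: list = field(default_factory=list)  # BaseObservation of edited reads
    filter_verdicts: dict = field(default_factory=dict)
    p_value: Optional[float] = None
    q_value: Optional[float] = None

    @property
    def passes(self) -> bool:
        return bool(self.filter_verdicts) and all(self.filter_verdicts.values())


@dataclass
class FilterConfig:
    """Thresholds of the editing-site filter cascade.

    Defaults follow the published tool: >=3 non-redundant supporting
    reads, editing level >=5 %, RNA base quality >=Q30 (error <0.1 %),
    DNA depth >=10x with homozygous posterior >=0.95, 6-base end clips,
    6-bp splice distance, homopolymer >=5, DNA depth cap at 2x the
    genome mean, realignment 95 %/50 % rules, BH FDR at 0.05.
    """

    min_support_reads: int = 3
    min_editing_level: float = 0.05
    min_base_qual: int = 30
    dna_min_base_qual: int = 20
    min_dna_depth: int = 10
    min_posterior: float = 0.95
    genotype_model: str = "bayes"
    clip_n: int = 6
    splice_dist: int = 6
    homopolymer_len: int = 5
    depth_cap_factor: float = 2.0
    depth_mode: str = "mean"  # 'mean' or 'peak'
    blat_second_ratio: float = 0.95
    qualify_fraction: float = 0.50
    fdr_cutoff: float = 0.05
    p_err: Optional[float] = None  # None -> derived from min_base_qual

    @property
    def err_upper(self) -> float:
        """Upper bound of per-base sequencing error among retained RNA bases."""
        if self.p_err is not None:
            return self.p_err
        return 10.0 ** (-self.min_base_qual / 10.0)


#: Ordered names of the cascade verdicts (reporting order).
CASCADE_FILTERS = (
    "dna_homozygous",
    "known_snp_excluded",
    "multi_type",
    "support",
    "level",
    "mid_read",
    "splice_distance",
    "homopolymer",
    "depth_cap",
    "realign_qualified",
    "fdr_pass",
)
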