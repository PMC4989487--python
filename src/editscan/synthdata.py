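"""Self-contained simulator: genome, genes, planted SNPs/edits, reads.

Emulates the data regime the detection cascade targets: a small
diploid-or-pooled genome carrying heterozygous SNPs (the confounder the
genotype models must reject), A-to-I editing sites with known true
levels on transcript strands, quality-dependent base errors, PCR
duplicates, and an optional near-identical paralogous copy of an edited
exon (the confounder the realignment filter must reject). Reads are
emitted truth-aligned (SAM) so no external mapper is needed; FASTQ is
written alongside for completeness.

All randomness flows from ``SimConfig.seed`` through one generator, so a
fixed seed reproduces every output byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pysam

from .alignio import Genome, Transcript
from .models import complement, revcomp

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SimConfig:
    """Study conditions of the standard synthetic dataset.

    Defaults describe a 50-kb single-chromosome genome with 10 multi-exon
    genes, diploid het SNPs at 1 per kb, 50 editing sites with levels
    uniform on [0.1, 0.9], 30x DNA / 50x RNA coverage of 90-bp reads at
    ~Q35, and 5 % PCR duplicates.
    """

    seed: int = 1234
    chrom: str = "chr1"
    genome_len: int = 50_000
    n_genes: int = 10
    ploidy: int = 2
    het_snp_rate: float = 0.001
    n_edit_sites: int = 50
    edit_level_dist: tuple = ("uniform", 0.1, 0.9)
    dna_depth: float = 30.0
    rna_depth: float = 50.0
    read_len: int = 90
    qual_mean: float = 35.0
    qual_sd: float = 3.0
    dup_rate: float = 0.05
    paired_rna: bool = False
    paralog_identity: Optional[float] = None  # e.g. 0.97; None disables
    paralog_len: int = 500

    def __post_init__(self):
        if self.genome_len < 10 * self.read_len:
            raise ValueError("genome_len must be >= 10 * read_len")
        for r in (self.het_snp_rate, self.dup_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.dna_depth <= 0 or self.rna_depth <= 0:
            raise ValueError("depths must be positive")


@dataclass
class TruthTable:
    """Ground truth of one simulated dataset."""

    snps: list = field(default_factory=list)  # (chrom,pos,ref,alt,alt_copies,ploidy)
    edits: list = field(default_factory=list)  # (chrom,pos,strand,type,level)
    paralog: Optional[tuple] = None  # ((src_start, src_end), (dst_start, dst_end))

    def snp_positions(self) -> set:
        return {(c, p) for c, p, *_ in self.snps}

    def edit_positions(self) -> set:
        return {(c, p) for c, p, *_ in self.edits}


@dataclass
class SimRead:
    name: str
    chrom: str
    start: int  # 1-based leftmost
    strand: str
    cigar: str
    seq: str  # forward genomic strand, as SAM stores it
    quals: list
    mate_flag: str = "single"
    mate_start: Optional[int] = None
    tlen: int = 0


# ---------------------------------------------------------------------------
# Reference and truth
# ---------------------------------------------------------------------------

def _random_seq(rng, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=n)]


def simulate_reference(cfg: SimConfig, rng: Optional[np.random.Generator] = None):
    """Random genome plus multi-exon gene models on both strands.

    Returns ``(genome: Genome, transcripts: dict, paralog: tuple|None)``.
    With a paralog configured, a ``paralog_len`` window centred on one exon
    of the first gene is copied into intergenic space at the configured
    identity; the source and copy intervals are returned.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    arr = _random_seq(rng, cfg.genome_len)
    margin = 1000
    reserve = cfg.paralog_len + 200 if cfg.paralog_identity is not None else 0
    cursor = margin
    transcripts: dict = {}
    for gi in range(cfg.n_genes):
        strand = "+" if rng.random() < 0.5 else "-"
        exons = []
        pos = cursor
        for ei in range(3):
            elen = int(rng.integers(150, 301))
            exons.append((pos + 1, pos + elen))
            pos += elen
            if ei < 2:
                pos += int(rng.integers(80, 201))
        if pos + margin + reserve > cfg.genome_len:
            raise ValueError("cannot pack genes into genome_len")
        tid = f"t{gi}"
        tr = Transcript(tid, f"g{gi}", cfg.chrom, strand, exons=exons)
        tlen = sum(e - s + 1 for s, e in exons)
        cds_len = 3 * ((tlen - 60) // 3)
        tr.cds = _transcript_slice_to_genomic(tr, 30, 30 + cds_len - 1)
        transcripts[tid] = tr
        cursor = pos + int(rng.integers(300, 601))
    paralog = None
    if cfg.paralog_identity is not None:
        src_tr = transcripts["t0"]
        es, ee = src_tr.exons[1]
        centre = (es + ee) // 2
        src_start = max(centre - cfg.paralog_len // 2, 1)
        src_end = src_start + cfg.paralog_len - 1
        dst_start = cfg.genome_len - cfg.paralog_len - 50
        copy = arr[src_start - 1:src_end].copy()
        n_sub = rng.binomial(cfg.paralog_len, 1.0 - cfg.paralog_identity)
        sub_pos = rng.choice(cfg.paralog_len, size=n_sub, replace=False)
        for sp in sub_pos:
            cur = copy[sp]
            choices = _BASES[_BASES != cur]
            copy[sp] = rng.choice(choices)
        arr[dst_start - 1:dst_start - 1 + cfg.paralog_len] = copy
        paralog = ((src_start, src_end),
                   (dst_start, dst_start + cfg.paralog_len - 1))
    genome = Genome({cfg.chrom: arr.tobytes().decode()})
    return genome, transcripts, paralog


def _transcript_slice_to_genomic(tr: Transcript, lo: int, hi: int) -> list:
    """Map a 0-based transcript-coordinate interval to genomic intervals.

    Transcript coordinates run 5'->3' on the transcript strand.
    """
    coords = transcript_coords(tr)
    sel = coords[lo:hi + 1]
    sel = sorted(sel)
    out = []
    run_start = prev = sel[0]
    for p in sel[1:]:
        if p == prev + 1:
            prev = p
            continue
        out.append((run_start, prev))
        run_start = prev = p
    out.append((run_start, prev))
    return out


def transcript_coords(tr: Transcript) -> list:
    """Genomic position of each transcript base, 5'->3' on the transcript."""
    coords = []
    for s, e in tr.exons:
        coords.extend(range(s, e + 1))
    if tr.strand == "-":
        coords = coords[::-1]
    return coords


def write_genome_fasta(genome: Genome, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom in genome.chroms():
            fh.write(f">{chrom}\n")
            seq = genome.sequence(chrom)
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_gtf(transcripts: dict, path) -> None:
    with open(path, "w") as fh:
        for tid in sorted(transcripts):
            tr = transcripts[tid]
            attrs = f'gene_id "{tr.gene_id}"; transcript_id "{tr.transcript_id}";'
            for s, e in tr.exons:
                fh.write(f"{tr.chrom}\tsim\texon\t{s}\t{e}\t.\t{tr.strand}\t."
                         f"\t{attrs}\n")
            frame_off = 0
            cds = tr.cds if tr.strand == "+" else tr.cds[::-1]
            for s, e in cds:
                fh.write(f"{tr.chrom}\tsim\tCDS\t{s}\t{e}\t.\t{tr.strand}"
                         f"\t{frame_off}\t{attrs}\n")
                frame_off = (3 - ((e - s + 1 - frame_off) % 3)) % 3


def _in_homopolymer(seq: str, pos: int, min_len: int = 5) -> bool:
    i = pos - 1
    b = seq[i]
    lo = i
    while lo > 0 and seq[lo - 1] == b:
        lo -= 1
    hi = i
    while hi + 1 < len(seq) and seq[hi + 1] == b:
        hi += 1
    return (hi - lo + 1) >= min_len


def plant_truth(cfg: SimConfig, genome: Genome, transcripts: dict,
                rng: Optional[np.random.Generator] = None,
                paralog: Optional[tuple] = None) -> TruthTable:
    """Place heterozygous SNPs genome-wide and A-to-I edits in transcripts.

    SNPs and edits are disjoint. Edits sit on transcript-strand adenosines
    (genomic A on + genes, T on - genes), away from homopolymer runs and
    at least 25 bp from transcript ends so reads can support them in their
    central half. With a paralog, at least three edits are forced into the
    copied source window.
    """
    rng = rng or np.random.default_rng(cfg.seed + 1)
    seq = genome.sequence(cfg.chrom)
    n_snp = rng.binomial(cfg.genome_len, cfg.het_snp_rate)
    snp_pos = set()
    truth = TruthTable(paralog=paralog)
    while len(snp_pos) < n_snp:
        p = int(rng.integers(1, cfg.genome_len + 1))
        snp_pos.add(p)
    for p in sorted(snp_pos):
        ref = seq[p - 1]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        alt_copies = int(rng.integers(1, cfg.ploidy)) if cfg.ploidy > 1 else 1
        truth.snps.append((cfg.chrom, p, ref, alt, alt_copies, cfg.ploidy))

    candidates: dict = {}  # pos -> strand
    for tid in sorted(transcripts):
        tr = transcripts[tid]
        coords = transcript_coords(tr)
        want = "A" if tr.strand == "+" else "T"
        for ti in range(25, len(coords) - 25):
            gp = coords[ti]
            if seq[gp - 1] != want:
                continue
            if gp in snp_pos or gp in candidates:
                continue
            if _in_homopolymer(seq, gp):
                continue
            candidates[gp] = tr.strand
    pool = sorted(candidates)
    if len(pool) < cfg.n_edit_sites:
        raise ValueError("not enough editable positions for requested edits")
    chosen = []
    if paralog is not None:
        (ss, se), _ = paralog
        in_par = [p for p in pool if ss + 25 <= p <= se - 25]
        if len(in_par) < 3:
            raise ValueError("paralog source window holds too few editable sites")
        chosen.extend(list(rng.choice(in_par, size=3, replace=False)))
    rest = [p for p in pool if p not in set(chosen)]
    chosen.extend(list(rng.choice(rest, size=cfg.n_edit_sites - len(chosen),
                                  replace=False)))
    kind = cfg.edit_level_dist[0]
    for p in sorted(int(x) for x in chosen):
        if kind == "fixed":
            level = float(cfg.edit_level_dist[1])
        elif kind == "uniform":
            level = float(rng.uniform(cfg.edit_level_dist[1],
                                      cfg.edit_level_dist[2]))
        elif kind == "beta":
            level = float(rng.beta(cfg.edit_level_dist[1],
                                   cfg.edit_level_dist[2]))
        else:
            raise ValueError(f"unknown edit_level_dist kind {kind!r}")
        truth.edits.append((cfg.chrom, p, candidates[p], "A-to-G", level))
    return truth


# ---------------------------------------------------------------------------
# Reads
# ---------------------------------------------------------------------------

def _draw_quals(rng, n: int, cfg: SimConfig) -> np.ndarray:
    q = np.rint(rng.normal(cfg.qual_mean, cfg.qual_sd, size=n))
    return np.clip(q, 2, 41).astype(int)


def _inject_errors(rng, seq: list, quals: np.ndarray) -> None:
    err = rng.random(len(seq)) < 10.0 ** (-quals / 10.0)
    for i in np.nonzero(err)[0]:
        cur = seq[i]
        seq[i] = str(rng.choice([b for b in "ACGT" if b != cur]))


def simulate_reads(cfg: SimConfig, genome: Genome, transcripts: dict,
                   truth: TruthTable, layer: str,
                   rng: Optional[np.random.Generator] = None,
                   seed: Optional[int] = None) -> list:
    """Draw truth-aligned reads for one layer ('dna' or 'rna').

    DNA fragments start uniformly on the genome; RNA fragments start
    uniformly within spliced transcripts and honour the dUTP strand rule
    (single-end reads antisense to the transcript; second-in-pair sense).
    At SNPs, alleles are drawn per genotype proportions in both layers;
    at edit sites, RNA reads carry the edited base with probability equal
    to the true level. Base errors follow the per-base quality; PCR
    duplicates re-emit a fragment with fresh errors.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 2 if seed is None else seed)
    snps = {p: (ref, alt, k, pl) for _, p, ref, alt, k, pl in truth.snps}
    edits = {p: (strand, level) for _, p, strand, _, level in truth.edits}
    seq = genome.sequence(cfg.chrom)
    reads: list = []

    def finish(name, positions, strand, mate_flag="single", frag_alleles=None):
        """Build one read over ascending genomic positions with fresh errors."""
        bases = [seq[p - 1] for p in positions]
        for i, p in enumerate(positions):
            if p in snps:
                ref, alt, kcop, pl = snps[p]
                allele = frag_alleles[p] if frag_alleles and p in frag_alleles \
                    else (alt if rng.random() < kcop / pl else ref)
                bases[i] = allele
            elif layer == "rna" and p in edits:
                estrand, level = edits[p]
                edited = frag_alleles.get(("edit", p)) if frag_alleles else None
                if edited is None:
                    edited = rng.random() < level
                if edited:
                    bases[i] = "G" if estrand == "+" else "C"
        quals = _draw_quals(rng, len(positions), cfg)
        _inject_errors(rng, bases, quals)
        cigar = _cigar_from_positions(positions)
        reads.append(SimRead(name=name, chrom=cfg.chrom, start=positions[0],
                             strand=strand, cigar=cigar, seq="".join(bases),
                             quals=list(quals), mate_flag=mate_flag))

    L = cfg.read_len
    if layer == "dna":
        n_reads = int(round(cfg.genome_len * cfg.dna_depth / L))
        for i in range(n_reads):
            start = int(rng.integers(1, cfg.genome_len - L + 2))
            strand = "+" if rng.random() < 0.5 else "-"
            positions = list(range(start, start + L))
            alleles = _fragment_alleles(rng, positions, snps, edits, layer)
            finish(f"d{i}", positions, strand, "single", alleles)
            if rng.random() < cfg.dup_rate:
                finish(f"d{i}dup", positions, strand, "single", alleles)
    else:
        trs = [transcripts[t] for t in sorted(transcripts)]
        coords = {tr.transcript_id: transcript_coords(tr) for tr in trs}
        lens = np.array([len(coords[tr.transcript_id]) for tr in trs], float)
        weights = lens / lens.sum()
        total = int(lens.sum())
        n_frags = int(round(total * cfg.rna_depth / L))
        if cfg.paired_rna:
            n_frags = max(n_frags // 2, 1)
        for i in range(n_frags):
            tr = trs[int(rng.choice(len(trs), p=weights))]
            c = coords[tr.transcript_id]
            if cfg.paired_rna:
                flen = min(int(rng.integers(2 * L, 2 * L + 60)), len(c))
                if flen < L:
                    continue
                fstart = int(rng.integers(0, len(c) - flen + 1))
                frag = c[fstart:fstart + flen]
                alleles = _fragment_alleles(rng, frag, snps, edits, layer)
                r2_pos = sorted(frag[:L])  # 5' end of the transcript fragment
                r1_pos = sorted(frag[-L:])
                r2_strand = tr.strand
                r1_strand = "-" if tr.strand == "+" else "+"
                finish(f"r{i}", r1_pos, r1_strand, "first", alleles)
                finish(f"r{i}", r2_pos, r2_strand, "second", alleles)
                if rng.random() < cfg.dup_rate:
                    finish(f"r{i}dup", r1_pos, r1_strand, "first", alleles)
                    finish(f"r{i}dup", r2_pos, r2_strand, "second", alleles)
            else:
                if len(c) < L:
                    continue
                fstart = int(rng.integers(0, len(c) - L + 1))
                frag = c[fstart:fstart + L]
                alleles = _fragment_alleles(rng, frag, snps, edits, layer)
                positions = sorted(frag)
                strand = "-" if tr.strand == "+" else "+"  # dUTP single-end
                finish(f"r{i}", positions, strand, "single", alleles)
                if rng.random() < cfg.dup_rate:
                    finish(f"r{i}dup", positions, strand, "single", alleles)
    reads.sort(key=lambda r: (r.chrom, r.start, r.name, r.mate_flag))
    _fill_mates(reads)
    return reads


def _fragment_alleles(rng, positions, snps, edits, layer) -> dict:
    """Fix SNP alleles and edit outcomes once per fragment so that mates and
    PCR duplicates agree."""
    out: dict = {}
    for p in positions:
        if p in snps:
            ref, alt, k, pl = snps[p]
            out[p] = alt if rng.random() < k / pl else ref
        elif layer == "rna" and p in edits:
            _, level = edits[p]
            out[("edit", p)] = rng.random() < level
    return out


def _cigar_from_positions(positions: list) -> str:
    parts = []
    run = 1
    for prev, cur in zip(positions, positions[1:]):
        if cur == prev + 1:
            run += 1
        else:
            parts.append(f"{run}M{cur - prev - 1}N")
            run = 1
    parts.append(f"{run}M")
    return "".join(parts)


def _fill_mates(reads: list) -> None:
    by_name: dict = {}
    for r in reads:
        if r.mate_flag != "single":
            by_name.setdefault(r.name, {})[r.mate_flag] = r
    for pair in by_name.values():
        if len(pair) == 2:
            r1, r2 = pair["first"], pair["second"]
            r1.mate_start, r2.mate_start = r2.start, r1.start


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------

def write_sam(reads: list, genome: Genome, path) -> None:
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": genome.length(c)} for c in genome.chroms()],
    }
    with pysam.AlignmentFile(str(path), "wh", header=header) as fh:
        tid = {c: i for i, c in enumerate(genome.chroms())}
        for r in reads:
            a = pysam.AlignedSegment()
            a.query_name = r.name
            a.reference_id = tid[r.chrom]
            a.reference_start = r.start - 1
            a.mapping_quality = 60
            a.cigarstring = r.cigar
            a.query_sequence = r.seq
            a.query_qualities = r.quals
            flag = 0
            if r.strand == "-":
                flag |= 16
            if r.mate_flag != "single":
                flag |= 1 | 2
                flag |= 64 if r.mate_flag == "first" else 128
                if r.mate_start is not None:
                    a.next_reference_id = tid[r.chrom]
                    a.next_reference_start = r.mate_start - 1
            a.flag = flag
            fh.write(a)


def write_fastq(reads: list, path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            seq, quals = r.seq, r.quals
            if r.strand == "-":  # emit as sequenced
                seq, quals = revcomp(seq), quals[::-1]
            name = r.name if r.mate_flag == "single" else \
                f"{r.name}/{'1' if r.mate_flag == 'first' else '2'}"
            fh.write(f"@{name}\n{seq}\n+\n"
                     + "".join(chr(q + 33) for q in quals) + "\n")


def write_truth(truth: TruthTable, snp_path, edit_path) -> None:
    with open(snp_path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\talt_copies\tploidy\n")
        for row in truth.snps:
            fh.write("\t".join(str(x) for x in row) + "\n")
    with open(edit_path, "w") as fh:
        fh.write("chrom\tpos\tstrand\tedit_type\ttrue_level\n")
        for row in truth.edits:
            fh.write("\t".join(str(x) for x in row) + "\n")


def simulate_dataset(cfg: SimConfig, outdir) -> dict:
    """Generate and write a complete dataset; returns paths and objects."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    genome, transcripts, paralog = simulate_reference(cfg, rng)
    truth = plant_truth(cfg, genome, transcripts, rng, paralog)
    dna = simulate_reads(cfg, genome, transcripts, truth, "dna", rng)
    rna = simulate_reads(cfg, genome, transcripts, truth, "rna", rng)
    paths = {
        "genome": outdir / "genome.fa", "gtf": outdir / "genes.gtf",
        "snps": outdir / "truth_snps.tsv", "edits": outdir / "truth_edits.tsv",
        "dna_sam": outdir / "dna.sam", "rna_sam": outdir / "rna.sam",
        "dna_fastq": outdir / "dna.fastq", "rna_fastq": outdir / "rna.fastq",
    }
    write_genome_fasta(genome, paths["genome"])
    write_gtf(transcripts, paths["gtf"])
    write_truth(truth, paths["snps"], paths["edits"])
    write_sam(dna, genome, paths["dna_sam"])
    write_sam(rna, genome, paths["rna_sam"])
    write_fastq(dna, paths["dna_fastq"])
    write_fastq(rna, paths["rna_fastq"])
    return {"cfg": cfg, "genome": genome, "transcripts": transcripts,
            "truth": truth, "dna_reads": dna, "rna_reads": rna,
            "paralog": paralog, "paths": paths}
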