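"""Per-sample pipeline orchestration and multi-sample integration.

``run_single_sample`` runs the full chain — read filtering, junction
lift-over, pileups, genotype calling, the editing filter cascade,
realignment and annotation — for one sample and returns its site table.
When several samples are available, passing sites are pooled into a map
of editable positions (excluding any position whose DNA is heterozygous
in any sample), each sample is then re-queried at those positions under
liberal criteria (>=1 supporting read, FDR-controlled), and the merged
table reports per-sample evidence and status.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from . import annotate as annomod
from .alignio import (Genome, filter_reads, load_gene_models, mean_coverage,
                      depth_histogram_peak, lift_junction_alignment, pileup,
                      read_alignments, ReadFilterPolicy)
from .editing import (CascadeContext, SpliceIndex, apply_filter_cascade,
                      bh_fdr, binom_error_test, detect_candidates, finalize_fdr)
from .genotype import call_genotype
from .models import FilterConfig, SiteObservations, complement
from .realign import Realigner, qualifying_fraction, realign_supporting_reads

log = logging.getLogger(__name__)


@dataclass
class SampleRun:
    """One sample's inputs and configuration."""

    sample_id: str
    dna_bam: str
    rna_bam: str
    ploidy: int = 2
    library: str = "stranded_dUTP"  # or 'unstranded'
    cfg: FilterConfig = field(default_factory=FilterConfig)


@dataclass
class SampleResult:
    sample_id: str
    table: pd.DataFrame
    candidates: list
    rna_sites: dict  # (chrom,pos) -> SiteObservations (RNA layer)
    dna_reads: list  # filtered DNA alignments (for re-pileup on demand)
    mean_dna_depth: float
    cfg: FilterConfig
    ploidy: int
    library: str


@dataclass(frozen=True)
class EditablePosition:
    chrom: str
    pos: int
    strand: str
    edit_type: str
    discovered_in: frozenset


def load_known_snps(path) -> set:
    """Known-SNP positions from VCF or a 3+-column TSV (chrom, pos, ref)."""
    positions = set()
    path = str(path)
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                continue
            try:
                positions.add((parts[0], int(parts[1])))
            except ValueError:
                continue
    return positions


def _segment_containing(aln, pos: int) -> Optional[str]:
    """Aligned read-sequence block containing a genomic position."""
    for qs, qe, rs, re in aln.aligned_blocks():
        if rs <= pos <= re:
            return aln.bases[qs - 1:qe]
    return None


def make_realign_check(rna_reads: list, realigner: Realigner,
                       cfg: FilterConfig):
    """Build the cascade's realignment predicate over filtered RNA reads."""
    by_key = {}
    for aln in rna_reads:
        by_key[(aln.read_id, aln.mate_flag)] = aln

    def check(cand):
        pairs = []
        for obs in cand.supporting_obs:
            aln = by_key.get((obs.read_id, obs.mate_flag))
            seg = _segment_containing(aln, cand.pos) if aln else None
            pairs.append((f"{obs.read_id}/{obs.mate_flag}", seg))
        res = realign_supporting_reads(pairs, realigner)
        return qualifying_fraction(cand.chrom, cand.pos, res,
                                   cfg.blat_second_ratio, cfg.qualify_fraction)

    return check


def run_single_sample(run: SampleRun, genome, transcripts: dict,
                      known_snps: Optional[set] = None,
                      junction_map: Optional[dict] = None,
                      realigner: Optional[Realigner] = None,
                      annotation: bool = True) -> SampleResult:
    """Execute the full detection pipeline for one sample.

    ``junction_map`` maps junction-contig names to JunctionRecord; RNA
    alignments on those contigs are lifted to genomic coordinates (reads
    not spanning the junction are dropped as redundant with genomic hits).
    Output is deterministic for fixed inputs and configuration.
    """
    cfg = run.cfg
    genome = genome if isinstance(genome, Genome) else Genome(genome)
    policy = ReadFilterPolicy(clip_n=cfg.clip_n)

    dna_raw = read_alignments(run.dna_bam)
    rna_raw = read_alignments(run.rna_bam)
    if junction_map:
        lifted = []
        for aln in rna_raw:
            jrec = junction_map.get(aln.chrom)
            if jrec is None:
                lifted.append(aln)
                continue
            aln.source = "junction"
            try:
                lifted.append(lift_junction_alignment(aln, jrec))
            except ValueError:
                log.debug("junction read %s not spanning; dropped", aln.read_id)
        rna_raw = sorted(lifted, key=lambda a: (a.chrom, a.start))

    dna_reads = filter_reads(dna_raw, policy)
    rna_reads = filter_reads(rna_raw, policy)
    if cfg.depth_mode == "peak":
        mean_depth = float(depth_histogram_peak(dna_reads, genome))
    else:
        mean_depth = mean_coverage(dna_reads, genome)

    splice_index = SpliceIndex(transcripts)
    rna_sites = pileup(rna_reads, genome, layer="rna",
                       min_base_qual=cfg.min_base_qual)
    cands = detect_candidates(
        rna_sites.values(), cfg, library=run.library,
        gene_strand_lookup=splice_index.gene_strands)

    positions = {(c.chrom, c.pos) for c in cands}
    dna_sites = pileup(dna_reads, genome, layer="dna",
                       min_base_qual=cfg.dna_min_base_qual,
                       positions=positions)
    for c in cands:
        site = dna_sites.get((c.chrom, c.pos))
        if site is None:
            site = SiteObservations(c.chrom, c.pos,
                                    genome.base(c.chrom, c.pos))
        c.dna_call = call_genotype(
            site, model=cfg.genotype_model, ploidy=run.ploidy,
            min_depth=cfg.min_dna_depth, min_posterior=cfg.min_posterior)

    realigner = realigner or Realigner(genome)
    ctx = CascadeContext(
        genome=genome, splice_index=splice_index, mean_dna_depth=mean_depth,
        cfg=cfg, known_snps=known_snps,
        realign_check=make_realign_check(rna_reads, realigner, cfg))
    attrition: dict = {}
    for c in cands:
        apply_filter_cascade(c, ctx)
        for name, ok in c.filter_verdicts.items():
            if not ok:
                attrition[name] = attrition.get(name, 0) + 1
    finalize_fdr(cands, cfg)
    for name, n in sorted(attrition.items()):
        log.info("sample %s: filter %s rejected %d candidates",
                 run.sample_id, name, n)

    feature_index = annomod.FeatureIndex(transcripts) if annotation else None
    rows = []
    for c in cands:
        dna_counts = _base_counts(dna_sites.get((c.chrom, c.pos)))
        row = {
            "chrom": c.chrom, "pos": c.pos, "strand": c.strand,
            "ref": c.ref_base, "edited": c.edited_base,
            "edit_type": c.edit_type,
            "dna_depth": c.dna_call.dna_depth,
            "dna_base_counts": dna_counts,
            "rna_depth": c.n_total, "k_edited": c.k_edited,
            "editing_level": round(c.editing_level, 6),
            "genotype_model": c.dna_call.model,
            "genotype": str(c.dna_call.best_genotype or ""),
            "posterior": c.dna_call.posterior,
            "p_value": c.p_value, "q_value": c.q_value,
        }
        row.update({f"filter_{k}": v for k, v in c.filter_verdicts.items()})
        row["pass"] = c.passes
        if feature_index is not None:
            row.update(annomod.annotate_candidate(c, feature_index,
                                                  transcripts, genome))
        rows.append(row)
    table = pd.DataFrame(rows)
    if not table.empty:
        table = table.sort_values(["chrom", "pos", "strand"],
                                  kind="mergesort").reset_index(drop=True)
    return SampleResult(run.sample_id, table, cands, rna_sites, dna_reads,
                        mean_depth, cfg, run.ploidy, run.library)


def _base_counts(site) -> str:
    counts = {b: 0 for b in "ACGT"}
    if site is not None:
        for o in site.dna_obs:
            if o.base in counts:
                counts[o.base] += 1
    return ",".join(f"{b}:{counts[b]}" for b in "ACGT")


# ---------------------------------------------------------------------------
# Multi-sample integration
# ---------------------------------------------------------------------------

def build_editable_positions(results: list, genome) -> list:
    """Pool passing sites across samples into editable positions.

    A position enters the map when it passed the full cascade in at least
    one sample, and is removed when the genomic DNA of any sample with
    sufficient depth fails homozygosity there (insufficient depth is not
    treated as evidence of heterozygosity).
    """
    if len(results) < 2:
        raise ValueError("editable-position map needs >= 2 samples")
    genome = genome if isinstance(genome, Genome) else Genome(genome)
    discovered: dict = {}
    for res in results:
        if res.table.empty:
            continue
        for _, row in res.table[res.table["pass"]].iterrows():
            key = (row["chrom"], int(row["pos"]), row["strand"],
                   row["edit_type"])
            discovered.setdefault(key, set()).add(res.sample_id)
    positions = {(c, p) for (c, p, _, _) in discovered}
    out = []
    hom_ok: dict = {}
    for res in results:
        dna_sites = pileup(res.dna_reads, genome, layer="dna",
                           min_base_qual=res.cfg.dna_min_base_qual,
                           positions=positions)
        for key in positions:
            site = dna_sites.get(key)
            depth = site.dna_depth if site else 0
            if depth < res.cfg.min_dna_depth:
                continue  # too shallow to judge in this sample
            call = call_genotype(site, model=res.cfg.genotype_model,
                                 ploidy=res.ploidy,
                                 min_depth=res.cfg.min_dna_depth,
                                 min_posterior=res.cfg.min_posterior)
            hom_ok[key] = hom_ok.get(key, True) and call.passes
    for key in sorted(discovered):
        chrom, pos, strand, etype = key
        if not hom_ok.get((chrom, pos), True):
            continue
        out.append(EditablePosition(chrom, pos, strand, etype,
                                    frozenset(discovered[key])))
    return sorted(out, key=lambda e: (e.chrom, e.pos, e.strand))


def retrieve_in_sample(positions: list, result: SampleResult,
                       fdr_cutoff: Optional[float] = None) -> pd.DataFrame:
    """Liberal re-query of one sample at the editable positions.

    At each position the sample reports its non-redundant RNA counts
    (k, n) for the mapped editing type; retrieval requires only k >= 1
    and a BH-adjusted q-value (computed over the retrieval set of this
    sample) at or below the cutoff. Sites failing even this report their
    counts with a not-detected status.
    """
    cfg = result.cfg
    cutoff = fdr_cutoff if fdr_cutoff is not None else cfg.fdr_cutoff
    discovered = set()
    if not result.table.empty:
        sub = result.table[result.table["pass"]]
        discovered = {(r["chrom"], int(r["pos"]), r["strand"])
                      for _, r in sub.iterrows()}
    rows = []
    pvals = []
    from .editing import _nonredundant

    for ep in positions:
        site = result.rna_sites.get((ep.chrom, ep.pos))
        reps = _nonredundant(site.rna_obs) if site else []
        ref_ts, alt_ts = ep.edit_type.split("-to-")
        alt_genomic = alt_ts if ep.strand != "-" else complement(alt_ts)
        n = len(reps)
        k = sum(1 for o in reps if o.base == alt_genomic)
        p = binom_error_test(k, n, cfg.err_upper) if n else 1.0
        pvals.append(p)
        rows.append({"chrom": ep.chrom, "pos": ep.pos, "strand": ep.strand,
                     "edit_type": ep.edit_type, "rna_depth": n, "k_edited": k,
                     "editing_level": (k / n) if n else 0.0, "p_value": p})
    qvals = bh_fdr(pvals)
    for row, q in zip(rows, qvals):
        row["q_value"] = q
        key = (row["chrom"], row["pos"], row["strand"])
        if key in discovered:
            row["status"] = "discovered"
        elif row["k_edited"] >= 1 and q <= cutoff:
            row["status"] = "retrieved"
        else:
            row["status"] = "absent"
    return pd.DataFrame(rows)


def merge_outputs(results: list, retrievals: dict,
                  positions: list) -> pd.DataFrame:
    """One row per editable position with per-sample evidence blocks.

    ``retrievals`` maps sample_id to the DataFrame from
    :func:`retrieve_in_sample` over the same ``positions``. Every
    discovered site of every sample appears; retrieval never removes one.
    Ordering is fixed (chrom, pos, strand) so identical inputs give
    byte-identical tables.
    """
    rows = []
    per_sample: dict = {}
    for res in results:
        ret = retrievals[res.sample_id]
        per_sample[res.sample_id] = {
            (r["chrom"], int(r["pos"]), r["strand"]): r
            for _, r in ret.iterrows()}
    disc_tables = {res.sample_id: res.table for res in results}
    for ep in sorted(positions, key=lambda e: (e.chrom, e.pos, e.strand)):
        row = {"chrom": ep.chrom, "pos": ep.pos, "strand": ep.strand,
               "edit_type": ep.edit_type,
               "discovered_in": ",".join(sorted(ep.discovered_in))}
        for res in results:
            sid = res.sample_id
            r = per_sample[sid].get((ep.chrom, ep.pos, ep.strand))
            dtab = disc_tables[sid]
            drow = None
            if not dtab.empty:
                m = dtab[(dtab["chrom"] == ep.chrom) & (dtab["pos"] == ep.pos)
                         & (dtab["strand"] == ep.strand)]
                if len(m):
                    drow = m.iloc[0]
            row[f"{sid}_dna_depth"] = (int(drow["dna_depth"])
                                       if drow is not None else "")
            row[f"{sid}_dna_counts"] = (drow["dna_base_counts"]
                                        if drow is not None else "")
            row[f"{sid}_rna_depth"] = int(r["rna_depth"]) if r is not None else 0
            row[f"{sid}_k"] = int(r["k_edited"]) if r is not None else 0
            row[f"{sid}_level"] = round(float(r["editing_level"]), 6) \
                if r is not None else 0.0
            row[f"{sid}_q"] = float(r["q_value"]) if r is not None else ""
            row[f"{sid}_status"] = r["status"] if r is not None else "absent"
        rows.append(row)
    return pd.DataFrame(rows)


def run_multi_sample(runs: list, genome, transcripts: dict,
                     known_snps: Optional[set] = None,
                     fdr_cutoff: Optional[float] = None) -> pd.DataFrame:
    """Discovery in every sample, editable-position pooling, liberal
    retrieval, and the merged per-site table."""
    genome = genome if isinstance(genome, Genome) else Genome(genome)
    realigner = Realigner(genome)
    results = [run_single_sample(r, genome, transcripts, known_snps,
                                 realigner=realigner) for r in runs]
    positions = build_editable_positions(results, genome)
    retrievals = {res.sample_id: retrieve_in_sample(positions, res, fdr_cutoff)
                  for res in results}
    return merge_outputs(results, retrievals, positions)
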