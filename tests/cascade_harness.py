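"""Engineered single-site scenarios for the filter cascade.

`make_scenario(fail=<filter name>)` builds a candidate plus context that
passes every cascade filter except the named one; `fail=None` passes all
eleven. Used by the cascade unit tests and the filter-isolation checks.
"""

from editscan.alignio import Genome, Transcript
from editscan.editing import (CascadeContext, SpliceIndex,
                              apply_filter_cascade, finalize_fdr)
from editscan.models import (BaseObservation, EditingCandidate, FilterConfig,
                             Genotype, GenotypeCall)

CHROM = "c"
EXON_SITE = 150  # inside exon 1
INTRON_NEAR_SPLICE = 203  # 3 bp into the intron
HOMOPOLYMER_SITE = 173  # centre of the planted AAAAA run


def _genome():
    # repeating ACGT: no homopolymer anywhere; plant one AAAAA run at 171-175
    seq = list("ACGT" * 500)
    seq[170:175] = list("AAAAA")
    return Genome({CHROM: "".join(seq)})


def _splice_index():
    tr = Transcript("t1", "g1", CHROM, "+", exons=[(101, 200), (301, 400)])
    return SpliceIndex({"t1": tr})


def _obs(base, read_pos=45, read_start=None, qual=35, idx=0):
    read_start = read_start if read_start is not None else 100 + idx
    return BaseObservation(base=base, qual=qual, read_id=f"r{idx}",
                           read_pos=read_pos, read_len=90,
                           read_start=read_start, read_end=read_start + 89,
                           read_strand="+", mate_flag="single")


def _candidate(pos, k=5, n=20, read_pos=45):
    support = [_obs("T", read_pos=read_pos, idx=i) for i in range(k)]
    return EditingCandidate(
        chrom=CHROM, pos=pos, strand="+", ref_base="C", edited_base="T",
        edit_type="C-to-T", n_total=n, k_edited=k, editing_level=k / n,
        supporting_obs=support)


def _dna_call(pos, passes=True, depth=30):
    return GenotypeCall(CHROM, pos, "bayes", Genotype(("A", "A")), 0.999,
                        depth, passes, passes)


def make_scenario(fail=None):
    """Return (candidate, context, cfg) engineered to fail only ``fail``."""
    cfg = FilterConfig()
    genome = _genome()
    splice = _splice_index()
    pos = EXON_SITE
    k, n, read_pos = 5, 20, 45
    dna_passes, dna_depth = True, 30
    known_snps = set()
    realign = lambda cand: (1.0, True)  # noqa: E731

    if fail == "dna_homozygous":
        dna_passes = False
    elif fail == "known_snp_excluded":
        known_snps = {(CHROM, pos)}
    elif fail == "support":
        k = 2
    elif fail == "level":
        k, n = 3, 100  # level 0.03 < 0.05 but support and p-value still fine
    elif fail == "mid_read":
        read_pos = 5  # outside the 23..68 central window of a 90-bp read
    elif fail == "splice_distance":
        pos = INTRON_NEAR_SPLICE
    elif fail == "homopolymer":
        pos = HOMOPOLYMER_SITE
    elif fail == "depth_cap":
        dna_depth = 100  # > 2 x mean depth of 30
    elif fail == "realign_qualified":
        realign = lambda cand: (0.25, False)  # noqa: E731
    elif fail == "fdr_pass":
        # raise the error floor so k=3/n=60 is explainable by error
        cfg = FilterConfig(p_err=0.02)
        k, n = 3, 60

    cand = _candidate(pos, k=k, n=n, read_pos=read_pos)
    if fail == "multi_type":
        cand.filter_verdicts["multi_type"] = False
    cand.dna_call = _dna_call(pos, passes=dna_passes, depth=dna_depth)
    ctx = CascadeContext(genome=genome, splice_index=splice,
                         mean_dna_depth=30.0, cfg=cfg, known_snps=known_snps,
                         realign_check=realign)
    return cand, ctx, cfg


def run_scenario(fail=None):
    cand, ctx, cfg = make_scenario(fail)
    apply_filter_cascade(cand, ctx)
    finalize_fdr([cand], cfg)
    return cand
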