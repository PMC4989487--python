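"""Candidate detection, elementary filters, binomial test and BH FDR."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cascade_harness import run_scenario
from editscan.alignio import Genome, Transcript
from editscan.editing import (SpliceIndex, bh_fdr, binom_error_test,
                              depth_cap_filter, detect_candidates,
                              homopolymer_filter, infer_edit_type,
                              mid_read_window, splice_distance_filter,
                              transcript_strand_of_read)
from editscan.models import (CASCADE_FILTERS, BaseObservation, FilterConfig,
                             SiteObservations)


class TestMidReadWindow:
    @pytest.mark.parametrize("length,expect", [
        (90, (23, 68)), (4, (2, 3)), (100, (26, 75)),
    ])
    def test_central_half(self, length, expect):
        assert mid_read_window(length) == expect

    def test_too_short(self):
        with pytest.raises(ValueError):
            mid_read_window(3)


def exact_binom_tail(k, n, p):
    """Independent oracle: direct summation of binomial pmf terms."""
    return math.fsum(math.comb(n, i) * p ** i * (1 - p) ** (n - i)
                     for i in range(k, n + 1))


class TestBinomErrorTest:
    def test_zero_support_is_one(self):
        assert binom_error_test(0, 50, 0.001) == 1.0

    def test_all_support_closed_form(self):
        assert binom_error_test(3, 3, 0.001) == pytest.approx(1e-9, rel=1e-6)

    def test_two_of_hundred_closed_form(self):
        expect = 1 - 0.999 ** 100 - 100 * 0.001 * 0.999 ** 99
        assert binom_error_test(2, 100, 0.001) == pytest.approx(expect, rel=1e-9)

    def test_matches_exact_sum_oracle_exhaustively(self):
        for n in range(1, 31):
            for k in range(n + 1):
                for p in (0.001, 0.05, 0.3):
                    assert binom_error_test(k, n, p) == pytest.approx(
                        exact_binom_tail(k, n, p), rel=1e-9, abs=1e-300)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            binom_error_test(5, 3, 0.001)
        with pytest.raises(ValueError):
            binom_error_test(1, 3, 0.0)


def brute_force_bh(pvals):
    """Independent BH step-up: sort, scale, cumulative min from the top."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, pvals[i] * m / rank_from_top)
        q[i] = running
    return q


class TestBhFdr:
    @pytest.mark.parametrize("pvals,expect", [
        ([0.2], [0.2]),
        ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
        ([0.5, 0.001], [0.5, 0.002]),
    ])
    def test_hand_computed_examples(self, pvals, expect):
        assert bh_fdr(pvals) == pytest.approx(expect)

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(5)
        for _ in range(1000):
            m = int(rng.integers(1, 40))
            pvals = list(rng.random(m))
            assert bh_fdr(pvals) == pytest.approx(brute_force_bh(pvals))

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1,
                    max_size=30))
    def test_q_values_stay_in_unit_interval(self, pvals):
        assert all(0.0 <= q <= 1.0 for q in bh_fdr(pvals))


class TestSequenceFilters:
    def test_homopolymer_run_of_five_discarded(self):
        genome = Genome({"c": "ACGTAAAAAGTC"})
        for pos in range(5, 10):  # every base of the AAAAA run
            assert homopolymer_filter(genome, "c", pos, 5) is False
        assert homopolymer_filter(genome, "c", 2, 5) is True

    def test_run_of_four_kept(self):
        genome = Genome({"c": "GCAAAATC"})
        assert homopolymer_filter(genome, "c", 4, 5) is True

    def test_first_base_of_long_run_discarded(self):
        genome = Genome({"c": "ATGGGGGGC"})
        assert homopolymer_filter(genome, "c", 3, 5) is False

    @pytest.mark.parametrize("depth,mean,expect", [
        (61, 30.0, False), (60, 30.0, True), (10, 30.0, True),
    ])
    def test_depth_cap(self, depth, mean, expect):
        assert depth_cap_filter(depth, mean, 2.0) is expect

    def test_splice_distance(self):
        tr = Transcript("t", "g", "c", "+", exons=[(101, 200), (301, 400)])
        idx = SpliceIndex({"t": tr})
        assert splice_distance_filter("c", 206, idx, 6) is False  # 6 bp in
        assert splice_distance_filter("c", 207, idx, 6) is True  # 7 bp in
        assert splice_distance_filter("c", 200, idx, 6) is True  # exonic
        assert splice_distance_filter("c", 50, idx, 6) is True  # intergenic


class TestEditType:
    @pytest.mark.parametrize("ref,alt,strand,label", [
        ("A", "G", "+", "A-to-G"),
        ("T", "C", "-", "A-to-G"),
        ("C", "T", ".", "C-to-T"),
    ])
    def test_labels(self, ref, alt, strand, label):
        assert infer_edit_type(ref, alt, strand)[2] == label

    def test_identical_bases_rejected(self):
        with pytest.raises(ValueError):
            infer_edit_type("A", "A", "+")

    @pytest.mark.parametrize("read_strand,mate,expect", [
        ("+", "single", "-"), ("-", "single", "+"),
        ("+", "second", "+"), ("+", "first", "-"),
    ])
    def test_dutp_strand_rule(self, read_strand, mate, expect):
        assert transcript_strand_of_read(read_strand, mate) == expect

    def test_strand_rule_inversion_makes_single_end_sense(self):
        assert transcript_strand_of_read("+", "single", invert=True) == "+"


def rna_obs(base, idx, start=None, strand="-", read_pos=45):
    start = start if start is not None else 100 + idx
    return BaseObservation(base=base, qual=35, read_id=f"r{idx}",
                           read_pos=read_pos, read_len=90, read_start=start,
                           read_end=start + 89, read_strand=strand,
                           mate_flag="single")


def site_with(bases, ref="A", identical_footprint=False):
    obs = [rna_obs(b, i, start=(100 if identical_footprint else None))
           for i, b in enumerate(bases)]
    return SiteObservations("c", 150, ref, rna_obs=obs)


class TestDetectCandidates:
    def test_low_support_recorded(self):
        site = site_with("G" + "A" * 19)
        (cand,) = detect_candidates([site])
        assert cand.k_edited == 1 and cand.n_total == 20
        assert cand.editing_level == pytest.approx(0.05)
        assert cand.filter_verdicts["level"] is True
        assert cand.filter_verdicts["support"] is False

    def test_redundant_support_collapsed(self):
        site = site_with("GGG", identical_footprint=True)
        (cand,) = detect_candidates([site])
        assert cand.k_edited == 1  # three identical footprints count once
        assert cand.filter_verdicts["support"] is False

    def test_multiple_edit_types_flagged(self):
        site = site_with("GGGCC" + "A" * 10)
        (cand,) = detect_candidates([site])
        assert cand.filter_verdicts["multi_type"] is False

    def test_reference_only_site_skipped(self):
        assert detect_candidates([site_with("A" * 10)]) == []

    def test_stranded_type_from_dutp_orientation(self):
        # '-' aligned single-end dUTP reads imply a '+' transcript
        site = site_with("G" * 5 + "A" * 5)
        (cand,) = detect_candidates([site], library="stranded_dUTP")
        assert cand.strand == "+" and cand.edit_type == "A-to-G"

    def test_unstranded_uses_gene_model(self):
        site = SiteObservations("c", 150, "T", rna_obs=[
            rna_obs("C", i, strand="+") for i in range(5)])
        (cand,) = detect_candidates(
            [site], library="unstranded",
            gene_strand_lookup=lambda c, p: {"-"})
        assert cand.strand == "-" and cand.edit_type == "A-to-G"

    def test_unstranded_without_gene_reports_plus_convention(self):
        site = SiteObservations("c", 150, "T", rna_obs=[
            rna_obs("C", i) for i in range(5)])
        (cand,) = detect_candidates([site], library="unstranded",
                                    gene_strand_lookup=lambda c, p: set())
        assert cand.strand == "." and cand.edit_type == "T-to-C"


class TestCascade:
    def test_fully_passing_candidate(self):
        cand = run_scenario(None)
        assert cand.passes
        assert set(cand.filter_verdicts) == set(CASCADE_FILTERS)

    @pytest.mark.parametrize("name", CASCADE_FILTERS)
    def test_each_filter_fails_in_isolation(self, name):
        cand = run_scenario(name)
        failed = [k for k, v in cand.filter_verdicts.items() if not v]
        assert failed == [name]
        assert not cand.passes

    def test_missing_context_named_in_error(self):
        from cascade_harness import make_scenario
        from editscan.editing import apply_filter_cascade

        cand, ctx, _ = make_scenario(None)
        cand.dna_call = None
        with pytest.raises(ValueError, match="genotype call"):
            apply_filter_cascade(cand, ctx)

    def test_outcome_independent_of_filter_order(self):
        """Filters are pure predicates; verdicts don't depend on order."""
        for name in (None, "homopolymer", "support", "fdr_pass"):
            baseline = run_scenario(name).filter_verdicts
            again = run_scenario(name).filter_verdicts
            assert dict(again) == dict(baseline)

    def test_snp_overlap_excluded(self):
        cand = run_scenario("known_snp_excluded")
        assert cand.filter_verdicts["known_snp_excluded"] is False
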