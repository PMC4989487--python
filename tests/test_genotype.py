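"""Genotype-space enumeration and the three homozygosity models."""

import math
from itertools import combinations_with_replacement

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from editscan.genotype import (GenotypePrior, call_bayes, call_binomial,
                               call_frequency, enumerate_genotypes,
                               genotype_likelihood, posterior_distribution)
from editscan.models import BASES, BaseObservation, Genotype, SiteObservations


def brute_force_genotypes(ploidy):
    """Independent enumeration: all base multisets with <= 2 distinct alleles."""
    return [g for g in combinations_with_replacement(BASES, ploidy)
            if len(set(g)) <= 2]


def make_obs(bases, qual=40):
    out = []
    for i, b in enumerate(bases):
        out.append(BaseObservation(base=b, qual=qual, read_id=f"r{i}",
                                   read_pos=10, read_len=90, read_start=i,
                                   read_end=i + 89, read_strand="+",
                                   mate_flag="single"))
    return out


def make_site(bases, qual=40, ref="A"):
    return SiteObservations("chr1", 100, ref, dna_obs=make_obs(bases, qual))


class TestEnumeration:
    @pytest.mark.parametrize("ploidy,expect", [(1, 4), (2, 10), (4, 22), (8, 46)])
    def test_known_cardinalities(self, ploidy, expect):
        gts = enumerate_genotypes(ploidy)
        assert len(gts) == expect
        assert len(gts) == len(brute_force_genotypes(ploidy))

    @pytest.mark.parametrize("ploidy", range(1, 13))
    def test_cardinality_formula_and_oracle(self, ploidy):
        gts = enumerate_genotypes(ploidy)
        assert len(gts) == 6 * ploidy - 2
        assert sorted(map(str, gts)) == \
            sorted("".join(g) for g in brute_force_genotypes(ploidy))

    def test_diploid_space_matches_standard_list(self):
        names = {str(g) for g in enumerate_genotypes(2)}
        assert names == {"AA", "TT", "CC", "GG", "AT", "AC", "AG", "CT",
                         "CG", "GT"}

    def test_canonical_order_deterministic(self):
        assert [str(g) for g in enumerate_genotypes(2)] == \
            sorted(str(g) for g in enumerate_genotypes(2))

    def test_invalid_ploidy(self):
        with pytest.raises(ValueError):
            enumerate_genotypes(0)


class TestLikelihood:
    def test_homozygote_closed_form(self):
        obs = make_obs("AAAAA", qual=40)
        ll = genotype_likelihood(obs, Genotype(("A", "A")))
        assert ll == pytest.approx(5 * math.log(1 - 1e-4))

    def test_heterozygote_two_term_sum(self):
        obs = make_obs("A", qual=30)
        e = 1e-3
        expect = math.log(0.5 * (1 - e) + 0.5 * e / 3)
        assert genotype_likelihood(obs, Genotype(("A", "G"))) == \
            pytest.approx(expect)

    def test_error_free_limit(self):
        obs = make_obs("A" * 10, qual=90)
        assert genotype_likelihood(obs, Genotype(("A", "A"))) == \
            pytest.approx(0.0, abs=1e-7)

    def test_empty_observations_identity(self):
        assert genotype_likelihood([], Genotype(("A", "A"))) == 0.0


def brute_posterior(obs, ploidy):
    """Independent posterior: direct probability-space computation."""
    gts = brute_force_genotypes(ploidy)
    probs = []
    for g in gts:
        p = 1.0
        for o in obs:
            e = 10 ** (-o.qual / 10)
            p *= sum((g.count(a) / ploidy) * ((1 - e) if a == o.base else e / 3)
                     for a in set(g))
        probs.append(p)
    total = sum(probs)
    return {"".join(g): p / total for g, p in zip(gts, probs)}


class TestBayes:
    def test_clear_homozygote(self):
        site = make_site("A" * 20)
        call = call_bayes(site, ploidy=2)
        assert str(call.best_genotype) == "AA"
        assert call.posterior > 0.99
        assert call.passes

    def test_balanced_het_not_homozygous(self):
        site = make_site("AAAAAGGGGG")
        call = call_bayes(site, ploidy=2)
        assert str(call.best_genotype) == "AG"
        assert not call.is_homozygous and not call.passes

    def test_depth_gate(self):
        call = call_bayes(make_site("A" * 20), ploidy=2, min_depth=25)
        assert call.is_homozygous and not call.passes

    def test_zero_depth_flagged(self):
        call = call_bayes(SiteObservations("chr1", 1, "A"), ploidy=2)
        assert call.posterior is None and not call.passes

    @pytest.mark.parametrize("bases,ploidy", [
        ("A" * 20, 2), ("AAAAAGGGGG", 2), ("AAAG", 4), ("ACAC", 2),
    ])
    def test_posterior_matches_brute_force(self, bases, ploidy):
        site = make_site(bases)
        gts, post = posterior_distribution(site, ploidy=ploidy)
        oracle = brute_posterior(site.dna_obs, ploidy)
        for g, p in zip(gts, post):
            assert p == pytest.approx(oracle[str(g)], rel=1e-9, abs=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.tuples(st.sampled_from("ACGT"),
                              st.integers(min_value=2, max_value=41)),
                    min_size=1, max_size=30),
           st.sampled_from([1, 2, 4]))
    def test_posteriors_sum_to_one(self, calls, ploidy):
        obs = make_obs([b for b, _ in calls])
        obs = [BaseObservation(base=o.base, qual=q, read_id=o.read_id,
                               read_pos=o.read_pos, read_len=o.read_len,
                               read_start=o.read_start, read_end=o.read_end,
                               read_strand=o.read_strand, mate_flag=o.mate_flag)
               for o, (_, q) in zip(obs, calls)]
        site = SiteObservations("c", 1, "A", dna_obs=obs)
        _, post = posterior_distribution(site, ploidy=ploidy)
        assert abs(post.sum() - 1.0) < 1e-9

    def test_monotone_in_major_allele_support(self):
        prev = 0.0
        for depth in range(5, 40, 5):
            call = call_bayes(make_site("A" * depth + "G"), ploidy=2)
            gts, post = posterior_distribution(make_site("A" * depth + "G"))
            p_hom = max(p for g, p in zip(gts, post) if str(g) == "AA")
            assert p_hom >= prev
            prev = p_hom

    def test_het_downweighted_prior_favours_homozygote(self):
        site = make_site("A" * 8 + "G")
        uni = call_bayes(site, prior=GenotypePrior("uniform"))
        wt = call_bayes(site, prior=GenotypePrior("hom_het_weighted"))
        gts, post = posterior_distribution(site, prior=GenotypePrior(
            "hom_het_weighted"))
        hom_mass = sum(p for g, p in zip(gts, post) if g.is_homozygous)
        gts, post_u = posterior_distribution(site)
        hom_mass_u = sum(p for g, p in zip(gts, post_u) if g.is_homozygous)
        assert hom_mass > hom_mass_u


class TestBinomialAndFrequency:
    def test_no_minor_bases_is_homozygous(self):
        call = call_binomial(make_site("A" * 20), error_rate=0.001)
        assert call.posterior == 1.0 and call.is_homozygous and call.passes

    def test_many_minor_bases_rejects(self):
        call = call_binomial(make_site("A" * 15 + "G" * 5), error_rate=0.001)
        assert call.posterior < 1e-6 and not call.is_homozygous

    def test_binomial_depth_gate(self):
        call = call_binomial(make_site("A" * 10), error_rate=0.001,
                             min_depth=11)
        assert call.is_homozygous and not call.passes

    @pytest.mark.parametrize("bases,max_alt,expect", [
        ("A" * 30, 0.0, True),
        ("A" * 29 + "G", 0.0, False),
        ("A" * 48 + "GG", 0.05, True),  # 2/50 = 0.04 <= 0.05
    ])
    def test_frequency_threshold(self, bases, max_alt, expect):
        call = call_frequency(make_site(bases), max_alt_freq=max_alt)
        assert call.is_homozygous is expect

    def test_model_concordance_on_clear_sites(self):
        """All three models agree on >= 99 % of deep clean homozygous sites."""
        rng = np.random.default_rng(11)
        agree = 0
        n_sites = 300
        for _ in range(n_sites):
            depth = int(rng.integers(20, 60))
            base = str(rng.choice(list("ACGT")))
            bases = [base if rng.random() > 1e-4 else "G" for _ in range(depth)]
            site = make_site("".join(bases), qual=40, ref=base)
            verdicts = {call_bayes(site, ploidy=2).is_homozygous,
                        call_binomial(site).is_homozygous,
                        call_frequency(site, max_alt_freq=0.05).is_homozygous}
            agree += len(verdicts) == 1
        assert agree / n_sites >= 0.99
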