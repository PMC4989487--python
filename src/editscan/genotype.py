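"""Ploidy-aware homozygous genotype calling from DNA-seq pileups.

An RNA/DNA mismatch can only be called an editing event if the genomic
DNA is reliably homozygous at that site. Three interchangeable models
decide this per site:

* **Bayesian** — posterior over the full genotype space given per-base
  qualities; the space holds the 4 homozygotes plus every biallelic
  composition, ``6p - 2`` genotypes for ploidy ``p`` (10 at p=2, 22 at
  p=4, matching a pool of two diploids).
* **Binomial** — is the minor-allele count consistent with sequencing
  error under ``Binomial(n, e)``?
* **Frequency** — simple alternative-allele-fraction threshold.

A call *passes* only if the best genotype is homozygous, its
posterior/score clears the threshold, and DNA depth is sufficient
(default >= 10 reads).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Optional

import numpy as np
from scipy.stats import binom

from .models import BASES, Genotype, GenotypeCall, SiteObservations


def enumerate_genotypes(ploidy: int) -> list:
    """All homozygous and biallelic genotypes for a given ploidy.

    For ploidy p this is the 4 homozygotes plus, for each of the 6
    unordered base pairs, the p-1 mixing ratios: 6p - 2 genotypes in
    canonical (lexicographic) order. Genotypes with more than two
    distinct alleles are never enumerated.
    """
    if ploidy < 1:
        raise ValueError("ploidy must be >= 1")
    gts = [Genotype((b,) * ploidy) for b in BASES]
    for a, b in combinations(BASES, 2):
        for i in range(1, ploidy):
            gts.append(Genotype((a,) * i + (b,) * (ploidy - i)))
    return sorted(gts, key=lambda g: str(g))


@dataclass
class GenotypePrior:
    """Prior over the genotype space: uniform, or heterozygote-downweighted."""

    kind: str = "uniform"
    het_weight: float = 0.001

    def weights(self, genotypes: list) -> np.ndarray:
        if self.kind == "uniform":
            w = np.ones(len(genotypes))
        elif self.kind == "hom_het_weighted":
            w = np.array([1.0 if g.is_homozygous else self.het_weight
                          for g in genotypes])
        else:
            raise ValueError(f"unknown prior kind {self.kind!r}")
        return w / w.sum()


def genotype_likelihood(obs: Iterable, g: Genotype) -> float:
    """Log-likelihood of the observed bases under genotype ``g``.

    P(b|g) = sum over alleles a of (count_g(a)/p) * ((1-e) if a==b else e/3),
    with e the per-base error probability from the Phred quality. Empty
    input returns 0 (the empty product).
    """
    fracs = g.allele_fractions()
    ll = 0.0
    for o in obs:
        e = o.error_prob
        p = 0.0
        for a, f in fracs.items():
            p += f * ((1.0 - e) if a == o.base else e / 3.0)
        if p <= 0.0:
            return float("-inf")
        ll += math.log(p)
    return ll


def _major_allele(obs: list, ref_base: str) -> Optional[str]:
    counts = {b: 0 for b in BASES}
    for o in obs:
        if o.base in counts:
            counts[o.base] += 1
    if not any(counts.values()):
        return None
    best = max(counts.values())
    tied = [b for b in BASES if counts[b] == best]
    if ref_base in tied:
        return ref_base
    return sorted(tied)[0]


def call_bayes(site_obs: SiteObservations, ploidy: int = 2,
               prior: Optional[GenotypePrior] = None,
               min_posterior: float = 0.95, min_depth: int = 10) -> GenotypeCall:
    """Report the maximum-posterior genotype and its homozygosity verdict."""
    prior = prior or GenotypePrior()
    obs = site_obs.dna_obs
    depth = len(obs)
    if depth == 0:
        return GenotypeCall(site_obs.chrom, site_obs.pos, "bayes", None, None,
                            0, False, False)
    gts = enumerate_genotypes(ploidy)
    logw = np.log(prior.weights(gts))
    logl = np.array([genotype_likelihood(obs, g) for g in gts])
    logpost = logw + logl
    logpost -= logpost.max()
    post = np.exp(logpost)
    post /= post.sum()
    best_i = int(np.argmax(post))  # argmax returns the first (canonical-order) tie
    best = gts[best_i]
    posterior = float(post[best_i])
    is_hom = best.is_homozygous
    passes = is_hom and posterior >= min_posterior and depth >= min_depth
    return GenotypeCall(site_obs.chrom, site_obs.pos, "bayes", best, posterior,
                        depth, is_hom, passes)


def posterior_distribution(site_obs: SiteObservations, ploidy: int = 2,
                           prior: Optional[GenotypePrior] = None):
    """Full posterior over the genotype space (genotypes, probabilities)."""
    prior = prior or GenotypePrior()
    gts = enumerate_genotypes(ploidy)
    logw = np.log(prior.weights(gts))
    logl = np.array([genotype_likelihood(site_obs.dna_obs, g) for g in gts])
    logpost = logw + logl
    logpost -= logpost.max()
    post = np.exp(logpost)
    post /= post.sum()
    return gts, post


def call_binomial(site_obs: SiteObservations, error_rate: Optional[float] = None,
                  alpha: float = 0.05, min_depth: int = 10,
                  min_error_rate: float = 1e-4) -> GenotypeCall:
    """Homozygosity test: are minor-allele bases consistent with sequencing error?

    With n the DNA depth and k the non-major-allele count, computes the
    upper tail P(X >= k) for X ~ Binomial(n, e). The site is accepted as
    homozygous for the major allele when that probability is >= alpha.
    By default e is the mean per-base error of the DNA observations
    (floored at ``min_error_rate``); pass ``error_rate`` to override.
    """
    obs = site_obs.dna_obs
    n = len(obs)
    if n == 0:
        return GenotypeCall(site_obs.chrom, site_obs.pos, "binomial", None, None,
                            0, False, False)
    major = _major_allele(obs, site_obs.ref_base)
    k = sum(1 for o in obs if o.base != major)
    if error_rate is None:
        error_rate = max(float(np.mean([o.error_prob for o in obs])),
                         min_error_rate)
    pval = float(binom.sf(k - 1, n, error_rate)) if k > 0 else 1.0
    is_hom = pval >= alpha
    ploidy_na = 2  # genotype reported as a diploid-style homozygote label
    best = Genotype((major,) * ploidy_na) if is_hom else None
    passes = is_hom and n >= min_depth
    return GenotypeCall(site_obs.chrom, site_obs.pos, "binomial", best, pval,
                        n, is_hom, passes)


def call_frequency(site_obs: SiteObservations, max_alt_freq: float = 0.0,
                   min_depth: int = 10) -> GenotypeCall:
    """Homozygosity by alternative-allele frequency threshold."""
    obs = site_obs.dna_obs
    n = len(obs)
    if n == 0:
        return GenotypeCall(site_obs.chrom, site_obs.pos, "frequency", None, None,
                            0, False, False)
    major = _major_allele(obs, site_obs.ref_base)
    k = sum(1 for o in obs if o.base != major)
    freq = k / n
    is_hom = freq <= max_alt_freq
    best = Genotype((major, major)) if is_hom else None
    passes = is_hom and n >= min_depth
    return GenotypeCall(site_obs.chrom, site_obs.pos, "frequency", best, freq,
                        n, is_hom, passes)


def call_genotype(site_obs: SiteObservations, model: str = "bayes",
                  ploidy: int = 2, min_depth: int = 10,
                  min_posterior: float = 0.95, **kwargs) -> GenotypeCall:
    """Dispatch to one of the three homozygosity models."""
    if model == "bayes":
        return call_bayes(site_obs, ploidy=ploidy, min_posterior=min_posterior,
                          min_depth=min_depth, **kwargs)
    if model == "binomial":
        return call_binomial(site_obs, min_depth=min_depth, **kwargs)
    if model == "frequency":
        return call_frequency(site_obs, min_depth=min_depth, **kwargs)
    raise ValueError(f"unknown genotype model {model!r}")
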