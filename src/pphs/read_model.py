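"""Read likelihoods under the symmetric per-base error model.

A read is an unordered sample from one of the two chromosomes, so given a
haplotype pair (h1, h2) and the sites S it covers,

    Pr(r | h1, h2) = 1/2 eps^d1 (1-eps)^(|S|-d1) + 1/2 eps^d2 (1-eps)^(|S|-d2)

with d_i the Hamming distance between r and h_i restricted to S. Every
multi-read quantity is accumulated in log space: at realistic coverage the
products run over hundreds of reads and underflow in linear space.

This module also precomputes the per-individual, per-site genotype
likelihood tables A[i, j, g] = prod_{r in R_ij} Pr(r | G_ij = g), the only
per-read quantity the allele-frequency EM ever needs, and the pattern-count
machinery used to vectorize mixture likelihoods over small site sets.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .types import HaplotypePair, Read, ReadSets

__all__ = [
    "read_pair_likelihood",
    "population_log_likelihood",
    "site_genotype_likelihood",
    "precompute_A",
    "genotype_loglik_table",
    "export_site_likelihoods",
    "pattern_counts",
    "pattern_hap_logterms",
    "pair_loglik_tensor",
]

# floor on eps inside log-space internals only; the exact API stays exact at eps=0
_EPS_FLOOR = 1e-12


def _hap_term(distance: int, n_sites: int, eps: float) -> float:
    """eps^d (1-eps)^(n-d), exact at eps = 0."""
    if eps == 0.0:
        return 1.0 if distance == 0 else 0.0
    return eps**distance * (1.0 - eps) ** (n_sites - distance)


def read_pair_likelihood(read: Read, pair: HaplotypePair, eps: float) -> float:
    """Probability of one read given a haplotype pair (equal-mixture model)."""
    if not (0 <= eps < 0.5):
        raise ValueError("eps must satisfy 0 <= eps < 0.5")
    if not read.observations:
        raise ValueError("empty read")
    d1 = d2 = 0
    for s, a in read.observations:
        if s >= len(pair):
            raise ValueError(f"read site {s} outside window of length {len(pair)}")
        d1 += a != pair.h1[s]
        d2 += a != pair.h2[s]
    n = len(read.observations)
    return 0.5 * _hap_term(d1, n, eps) + 0.5 * _hap_term(d2, n, eps)


def population_log_likelihood(
    reads: ReadSets | Sequence[Read], pairs: Sequence[HaplotypePair], eps: float
) -> float:
    """Log-likelihood of all reads given one haplotype pair per individual."""
    if isinstance(reads, ReadSets):
        read_list = reads.to_reads()
    else:
        read_list = list(reads)
    by_id = {p.individual_id: p for p in pairs}
    total = 0.0
    for r in read_list:
        total += float(np.log(read_pair_likelihood(r, by_id[r.individual_id], eps)))
    return total


def site_genotype_likelihood(allele_observed: int, g: int, eps: float) -> float:
    """Pr(observe allele | genotype g) for a single site."""
    if allele_observed not in (0, 1) or g not in (0, 1, 2):
        raise ValueError("allele must be 0/1, genotype 0/1/2")
    if g == 1:
        return 0.5
    correct = 0 if g == 0 else 1
    return 1.0 - eps if allele_observed == correct else eps


def genotype_loglik_table(reads: ReadSets, eps: float) -> np.ndarray:
    """log A[i, j, g] for all individuals and sites, shape (n, m, 3).

    A[i, j, g] = 1 (log = 0) when individual i has no read covering site j.
    """
    n, m = reads.n, reads.m
    logA = np.zeros((n, m, 3))
    ridx, site = np.nonzero(reads.alleles >= 0)
    if ridx.size == 0:
        return logA
    ind = reads.read_individual[ridx]
    allele = reads.alleles[ridx, site].astype(np.int64)

    with np.errstate(divide="ignore"):
        log_match = np.log(1.0 - eps)
        log_miss = np.log(eps) if eps > 0 else -np.inf
    # g = 0: correct allele is 0; g = 2: correct allele is 1; g = 1: always 1/2
    contrib0 = np.where(allele == 0, log_match, log_miss)
    contrib2 = np.where(allele == 1, log_match, log_miss)
    np.add.at(logA[:, :, 0], (ind, site), contrib0)
    np.add.at(logA[:, :, 1], (ind, site), np.log(0.5))
    np.add.at(logA[:, :, 2], (ind, site), contrib2)
    return logA


def precompute_A(reads: ReadSets, j: int, eps: float) -> np.ndarray:
    """Genotype likelihood triples A[i, j, g] at one SNP, shape (n, 3)."""
    sub = reads.restrict_sites([j])
    return np.exp(genotype_loglik_table(sub, eps)[:, 0, :])


def export_site_likelihoods(reads: ReadSets, eps: float) -> np.ndarray:
    """Per-site, per-individual likelihoods over H_i in {(0,0), (1,0), (1,1)}.

    Shape (n, m, 3); identical to the genotype-likelihood table with the
    unordered-pair indexing (0,0) -> g=0, (1,0) -> g=1, (1,1) -> g=2. This is
    what a scaffold phaser consumes (VCF GL triples after log10 scaling).
    """
    return np.exp(genotype_loglik_table(reads, eps))


# ---------------------------------------------------------------------------
# pattern-count machinery for vectorized mixture likelihoods on few sites
# ---------------------------------------------------------------------------


def pattern_counts(reads: ReadSets, sites: Sequence[int]) -> np.ndarray:
    """Count read observation patterns over a small site set.

    A pattern encodes, per site, "missing" / "allele 0" / "allele 1" in base
    3; code 0 (all missing) is excluded. Returns an (n, 3^s - 1) int matrix
    whose [i, p-1] entry is the number of reads of individual i showing
    pattern p. Restricting likelihoods to a site set only depends on these
    counts, which makes the EM inner loops pure matrix algebra.
    """
    sites = list(sites)
    s = len(sites)
    sub = reads.alleles[:, sites].astype(np.int64) + 1  # 0 missing, 1/2 alleles
    codes = sub @ (3 ** np.arange(s))
    keep = codes > 0
    out = np.zeros((reads.n, 3**s - 1), dtype=np.int64)
    np.add.at(out, (reads.read_individual[keep], codes[keep] - 1), 1)
    return out


def pattern_hap_logterms(haplotypes: np.ndarray, eps: float) -> np.ndarray:
    """log eps^d (1-eps)^(c-d) for every pattern x haplotype, shape (3^s-1, K).

    ``haplotypes`` is (K, s) over the same site order used by pattern_counts;
    d is the Hamming distance between the pattern's observed alleles and the
    haplotype, c the number of observed sites. eps is floored at 1e-12 so
    log terms stay finite for noiseless data.
    """
    haps = np.asarray(haplotypes, dtype=np.int64)
    K, s = haps.shape
    eff = max(eps, _EPS_FLOOR)
    P = 3**s - 1
    codes = np.arange(1, P + 1)
    digits = (codes[:, None] // (3 ** np.arange(s))[None, :]) % 3  # (P, s)
    observed = digits > 0
    allele = digits - 1  # valid where observed
    match = (allele[:, None, :] == haps[None, :, :]) & observed[:, None, :]
    mismatch = (allele[:, None, :] != haps[None, :, :]) & observed[:, None, :]
    return match.sum(axis=2) * np.log(1.0 - eff) + mismatch.sum(axis=2) * np.log(eff)


def pair_loglik_tensor(
    reads: ReadSets, sites: Sequence[int], haplotypes: np.ndarray, eps: float
) -> np.ndarray:
    """log Pr(R_i restricted to sites | h_a, h_b) for all pairs, shape (n, K, K)."""
    counts = pattern_counts(reads, sites)
    lt = pattern_hap_logterms(haplotypes, eps)  # (P, K)
    log_pair = np.logaddexp(lt[:, :, None], lt[:, None, :]) + np.log(0.5)  # (P, K, K)
    K = lt.shape[1]
    return (counts @ log_pair.reshape(counts.shape[1], K * K)).reshape(-1, K, K)
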