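"""Accuracy metrics: SM (switch + mismatch) error, tree accuracy, MinSingleErr.

The SM metric counts, over the truth-heterozygous sites of one individual,
the genotype disagreements (mismatches M: the inferred genotype is not
heterozygous where the truth is) and, over the remaining het sites in
order, the number of adjacent phase-orientation flips (switches S). The
two canonical cases: truth (11, 00) phased as (10, 01) is one switch;
phased as (11, 01) is one mismatch.

Tree accuracy is the truth-frequency mass of the haplotypes shared by the
true and the reconstructed tree. MinSingleErr is the single-individual
lower bound: per site, call the MAP genotype from the read likelihoods; a
called het site is phased correctly by construction, so its error and
no-call rates bound any one-individual-at-a-time assembly method.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .read_model import genotype_loglik_table
from .types import HaplotypePair, PhyloTree, ReadSets

__all__ = ["SMReport", "TreeAccuracy", "sm_error", "tree_accuracy", "min_single_err"]


@dataclass(frozen=True)
class SMReport:
    switches: int
    mismatches: int
    sites_evaluated: int
    hom_mismatches: int = 0  # truth hom called het; reported separately

    @property
    def total(self) -> int:
        return self.switches + self.mismatches


@dataclass(frozen=True)
class TreeAccuracy:
    shared_mass: float


def sm_error(truth: HaplotypePair, inferred: HaplotypePair) -> SMReport:
    """Switch + mismatch errors of one individual's inferred pair."""
    if len(truth) != len(inferred):
        raise ValueError("truth and inferred pairs must have equal length")
    tg = truth.genotypes()
    ig = inferred.genotypes()

    hom_mm = sum(1 for t, g in zip(tg, ig) if t != 1 and g == 1)

    mismatches = 0
    orientations = []
    for j, t in enumerate(tg):
        if t != 1:
            continue
        if ig[j] != 1:
            mismatches += 1
            continue
        orientations.append(0 if inferred.h1[j] == truth.h1[j] else 1)
    switches = sum(1 for a, b in zip(orientations, orientations[1:]) if a != b)
    het_sites = sum(1 for t in tg if t == 1)
    return SMReport(switches, mismatches, het_sites, hom_mm)


def tree_accuracy(true_tree: PhyloTree, inferred_tree: PhyloTree) -> TreeAccuracy:
    """Truth-frequency mass of haplotypes recovered by the reconstruction."""
    if true_tree.frequencies is None:
        raise ValueError("true tree has no frequencies")
    true_haps = true_tree.haplotypes()
    shared = inferred_tree.haplotype_set()
    mass = sum(
        float(true_tree.frequencies[v])
        for v, h in enumerate(true_haps)
        if h in shared
    )
    return TreeAccuracy(mass)


def min_single_err(
    reads: ReadSets, individual: int, eps: float, truth: HaplotypePair
) -> tuple[float, float]:
    """Error and no-call rates of the per-site MAP-genotype lower bound.

    No-call at sites without a covering read; an error is a called MAP
    genotype differing from the truth genotype. Likelihood ties are broken
    toward heterozygous (a called het is phased for free under this bound).
    Rates are over all window sites.
    """
    m = reads.m
    logA = genotype_loglik_table(reads, eps)[individual]  # (m, 3)
    covered = np.zeros(m, dtype=bool)
    mask = reads.read_individual == individual
    if mask.any():
        covered = (reads.alleles[mask] >= 0).any(axis=0)
    tg = truth.genotypes()

    errors = 0
    no_calls = 0
    for j in range(m):
        if not covered[j]:
            no_calls += 1
            continue
        row = logA[j]
        best = max(row)
        # tie toward het (g = 1), then arbitrary but fixed order
        candidates = [g for g in (1, 0, 2) if row[g] >= best - 1e-12]
        call = candidates[0]
        if call != tg[j]:
            errors += 1
    return errors / m, no_calls / m
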