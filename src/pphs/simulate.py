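"""Synthetic data: perfect-phylogeny haplotype pools, diploids, noisy reads.

The generator emulates what a low-mutation-rate coalescent simulation
provides as input to the phaser: a pool of ``m + 1`` haplotypes related by
a perfect phylogeny (every SNP arose exactly once on the genealogy), each
with a population frequency bounded below by ``min_hap_freq``, plus a
shotgun sequencing process with uniform read starts and a constant
per-base error rate.
"""

from __future__ import annotations

import numpy as np

from .types import HaplotypePair, PhyloTree, Read, ReadSets, SimulationParams

__all__ = [
    "simulate_tree",
    "sample_individuals",
    "simulate_reads",
    "simulate_readsets",
    "simulate_dataset",
]


def simulate_tree(m_snps: int, min_hap_freq: float, rng: np.random.Generator) -> PhyloTree:
    """Draw a random perfect-phylogeny tree over ``m_snps`` SNPs.

    Topology: each SNP edge attaches to a uniformly random existing node, so
    the tree has exactly ``m + 1`` nodes / haplotypes. Frequencies: uniform
    on the sub-simplex {p : p_v >= min_hap_freq}, realized as the affine map
    ``min_freq + (1 - (m+1)*min_freq) * Dirichlet(1,...,1)`` (the exact
    conditional law of a flat Dirichlet given the floor).
    """
    if m_snps < 1:
        raise ValueError("need at least one SNP")
    n_nodes = m_snps + 1
    if min_hap_freq * n_nodes > 1 + 1e-12:
        raise ValueError("min_hap_freq infeasible: min_freq*(m+1) must be <= 1")

    parents: list[int | None] = [None]
    edge_snps: list[int | None] = [None]
    for j in range(m_snps):
        parents.append(int(rng.integers(0, len(parents))))
        edge_snps.append(j)

    slack = 1.0 - min_hap_freq * n_nodes
    p = min_hap_freq + slack * rng.dirichlet(np.ones(n_nodes))
    tree = PhyloTree(snps=list(range(m_snps)), parents=parents, edge_snps=edge_snps, frequencies=p)
    tree.validate()
    return tree


def tree_allele_frequencies(tree: PhyloTree) -> np.ndarray:
    """Population frequency of allele 1 at each SNP implied by the tree."""
    haps = np.asarray(tree.haplotypes(), dtype=float)
    return haps.T @ tree.frequencies


def sample_individuals(tree: PhyloTree, n: int, rng: np.random.Generator) -> list[HaplotypePair]:
    """Draw ``n`` diploids, each haplotype i.i.d. from the node frequencies."""
    if tree.frequencies is None:
        raise ValueError("tree has no frequencies")
    haps = tree.haplotypes()
    idx = rng.choice(tree.n_nodes, size=(n, 2), p=tree.frequencies)
    return [
        HaplotypePair(f"ind{i}", haps[idx[i, 0]], haps[idx[i, 1]])
        for i in range(n)
    ]


def _simulate_read_arrays(
    pair: HaplotypePair, params: SimulationParams, rng: np.random.Generator
) -> np.ndarray:
    """Allele matrix (n_reads, m) with -1 at uncovered sites; empty reads dropped."""
    G, l, eps = params.region_length, params.read_length_l, params.error_rate
    n_reads = int(round(params.coverage_k * G / l))
    pos = np.asarray(params.snp_positions)
    m = params.m_snps

    starts = rng.integers(1, G - l + 2, size=n_reads)
    source = rng.integers(0, 2, size=n_reads)
    haps = np.asarray([pair.h1, pair.h2], dtype=np.int8)

    lo = np.searchsorted(pos, starts)
    hi = np.searchsorted(pos, starts + l, side="left")

    counts = hi - lo
    total = int(counts.sum())
    alleles = np.full((n_reads, m), -1, dtype=np.int8)
    if total:
        ridx = np.repeat(np.arange(n_reads), counts)
        offsets = np.repeat(np.cumsum(counts) - counts, counts)
        site = np.arange(total) - offsets + np.repeat(lo, counts)
        truth = haps[source[ridx], site]
        flip = rng.random(total) < eps
        alleles[ridx, site] = np.where(flip, 1 - truth, truth)
    return alleles[counts > 0]


def simulate_reads(
    pair: HaplotypePair, params: SimulationParams, rng: np.random.Generator
) -> list[Read]:
    """Shotgun reads for one individual.

    The read count is deterministic, ``round(k * region_length / l)``; each
    read starts uniformly in the region, copies a fair-coin chromosome, and
    flips every covered SNP allele independently with probability eps.
    Reads covering no SNP are dropped.
    """
    if len(pair) != params.m_snps:
        raise ValueError("haplotype length does not match m_snps")
    alleles = _simulate_read_arrays(pair, params, rng)
    reads = []
    for k in range(alleles.shape[0]):
        sites = np.flatnonzero(alleles[k] >= 0)
        obs = tuple((int(s), int(alleles[k, s])) for s in sites)
        reads.append(Read(pair.individual_id, f"{pair.individual_id}_r{k}", obs))
    return reads


def simulate_readsets(
    pairs: list[HaplotypePair], params: SimulationParams, rng: np.random.Generator
) -> ReadSets:
    """Vectorized cohort sequencing: one ReadSets for all individuals."""
    blocks = []
    read_ind = []
    for i, pair in enumerate(pairs):
        if len(pair) != params.m_snps:
            raise ValueError("haplotype length does not match m_snps")
        a = _simulate_read_arrays(pair, params, rng)
        blocks.append(a)
        read_ind.append(np.full(a.shape[0], i, dtype=np.int64))
    alleles = (
        np.concatenate(blocks) if blocks else np.empty((0, params.m_snps), dtype=np.int8)
    )
    ind = np.concatenate(read_ind) if read_ind else np.empty(0, dtype=np.int64)
    names = [p.individual_id for p in pairs]
    return ReadSets(names, params.m_snps, alleles, ind)


def simulate_dataset(
    params: SimulationParams, rng: np.random.Generator | None = None
) -> tuple[PhyloTree, list[HaplotypePair], ReadSets]:
    """Full simulation: tree, truth diploids, and cohort reads."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    tree = simulate_tree(params.m_snps, params.min_hap_freq, rng)
    pairs = sample_individuals(tree, params.n_individuals, rng)
    reads = simulate_readsets(pairs, params, rng)
    return tree, pairs, reads
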