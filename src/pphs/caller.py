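"""Per-window haplotype assignment: MAP over tree-derived candidates.

The candidate pool is the tree's node haplotypes (the list L) plus every
one-mutation neighbour of an L member (the relaxation that tolerates a
single recurrent mutation per haplotype). Each individual receives the
unordered candidate pair maximizing prior(h1) * prior(h2) * Pr(R_i | h1, h2).
Priors are the mode of a Dirichlet posterior over haplotype frequencies,
p_h proportional to n_h + alpha_h - 1, where n_h counts the haplotypes
already assigned to earlier individuals and alpha puts more weight on L
members (alpha1) than on derived ones (alpha2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .read_model import pair_loglik_tensor
from .types import HaplotypePair, PhyloTree, ReadSets

__all__ = ["CandidatePool", "build_candidate_pool", "compute_priors", "assign_pair", "phase_window"]

DEFAULT_ALPHA1 = 2.0
DEFAULT_ALPHA2 = 1.2


@dataclass
class CandidatePool:
    """Candidate haplotypes for one window with their Dirichlet weights."""

    haplotypes: list[tuple[int, ...]]  # L members first, then derived
    n_in_L: int
    alphas: np.ndarray
    counts: np.ndarray  # usage over already-phased individuals

    @property
    def in_L(self) -> list[tuple[int, ...]]:
        return self.haplotypes[: self.n_in_L]

    @property
    def derived(self) -> list[tuple[int, ...]]:
        return self.haplotypes[self.n_in_L :]

    def __len__(self) -> int:
        return len(self.haplotypes)


def build_candidate_pool(
    tree: PhyloTree, alpha1: float = DEFAULT_ALPHA1, alpha2: float = DEFAULT_ALPHA2
) -> CandidatePool:
    """List L = tree node haplotypes; derived = their Hamming-1 neighbours.

    Derived haplotypes already present in L are dropped; duplicates among
    the derived are kept once. alpha weights must exceed 1 so the Dirichlet
    mode stays a proper distribution even for never-used candidates.
    """
    if alpha1 <= 1 or alpha2 <= 1:
        raise ValueError("Dirichlet weights must be > 1")
    L = tree.haplotypes()
    in_L = set(L)
    derived: dict[tuple[int, ...], None] = {}
    for h in L:
        for j in range(len(h)):
            nb = list(h)
            nb[j] = 1 - nb[j]
            t = tuple(nb)
            if t not in in_L:
                derived.setdefault(t, None)
    ordered = L + sorted(derived)
    alphas = np.concatenate(
        [np.full(len(L), float(alpha1)), np.full(len(derived), float(alpha2))]
    )
    return CandidatePool(ordered, len(L), alphas, np.zeros(len(ordered), dtype=np.int64))


def compute_priors(pool: CandidatePool) -> np.ndarray:
    """Dirichlet-posterior mode: p_h proportional to n_h + alpha_h - 1."""
    raw = pool.counts + pool.alphas - 1.0
    if np.any(raw <= 0):
        raise ValueError("counts + alpha - 1 must stay positive")
    return raw / raw.sum()


def assign_pair(
    reads: ReadSets,
    individual: int,
    pool: CandidatePool,
    priors: np.ndarray,
    eps: float,
) -> HaplotypePair:
    """MAP haplotype pair for one individual by exhaustive pair search.

    Ties are broken lexicographically on (h1, h2); an individual without
    reads receives the two highest-prior candidates.
    """
    if len(pool) == 0:
        raise ValueError("empty candidate pool")
    name = reads.individuals[individual]
    order = np.arange(len(pool))

    has_reads = np.any(
        (reads.read_individual == individual) & (reads.alleles >= 0).any(axis=1)
    )
    if not has_reads:
        # no informative reads: top-2 priors, lexicographic tie-break
        rank = sorted(order, key=lambda k: (-priors[k], pool.haplotypes[k]))
        a, b = rank[0], rank[1] if len(pool) > 1 else rank[0]
        h1, h2 = sorted([pool.haplotypes[a], pool.haplotypes[b]])
        return HaplotypePair(name, h1, h2)

    haps = np.asarray(pool.haplotypes)
    L = pair_loglik_tensor(reads, list(range(reads.m)), haps, eps)[individual]
    with np.errstate(divide="ignore"):
        lp = np.log(priors)
    score = L + lp[:, None] + lp[None, :]

    best = None
    best_score = -np.inf
    K = len(pool)
    for a in range(K):
        for b in range(a, K):
            s = score[a, b]
            if s > best_score + 1e-12:
                best_score = s
                best = (a, b)
            elif abs(s - best_score) <= 1e-12 and best is not None:
                cand = tuple(sorted([pool.haplotypes[a], pool.haplotypes[b]]))
                cur = tuple(sorted([pool.haplotypes[best[0]], pool.haplotypes[best[1]]]))
                if cand < cur:
                    best = (a, b)
    h1, h2 = sorted([pool.haplotypes[best[0]], pool.haplotypes[best[1]]])
    return HaplotypePair(name, h1, h2)


def phase_window(
    reads: ReadSets,
    tree: PhyloTree,
    alpha1: float = DEFAULT_ALPHA1,
    alpha2: float = DEFAULT_ALPHA2,
    eps: float = 0.01,
    order: list[int] | None = None,
) -> list[HaplotypePair]:
    """Assign pairs to all individuals sequentially, updating the priors.

    Individuals are processed in input order (or the given order); after
    each assignment the usage counts of the two chosen haplotypes are
    incremented, so later individuals see reinforced priors.
    """
    pool = build_candidate_pool(tree, alpha1, alpha2)
    index = {h: k for k, h in enumerate(pool.haplotypes)}
    if order is None:
        order = list(range(reads.n))
    results: list[HaplotypePair | None] = [None] * reads.n
    for i in order:
        priors = compute_priors(pool)
        pair = assign_pair(reads, i, pool, priors, eps)
        pool.counts[index[pair.h1]] += 1
        pool.counts[index[pair.h2]] += 1
        results[i] = pair
    return results  # type: ignore[return-value]
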