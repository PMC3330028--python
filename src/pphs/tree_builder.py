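"""Perfect-phylogeny tree reconstruction within a SNP window.

The reconstruction is recursive: estimate each SNP's minor-allele
frequency, anchor the SNP with the largest frequency (``j*``) as the edge
adjacent to the all-zero root, split the remaining SNPs into the side
subtree T1 (not below j*) and the descendant subtree T2 (below j*), and
recurse on both sides.

Two partitioning procedures are provided. PPHS-2 decides each SNP
independently by comparing the maximized likelihood of the two minimal
two-SNP models (j beside j* vs j below j*). PPHS-3 scores every pair of
SNPs jointly: for each of the four side configurations it fits the small
three-SNP subtrees by EM, averages their likelihoods into four weighted
graphs, and searches for the partition maximizing the summed consistent
weights — exactly for small windows, by random-subset majority vote for
large ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np

from .allele_freq import AlleleFreqEstimate, em_allele_frequency, naive_frequency_init, select_root_snp
from .read_model import genotype_loglik_table, pair_loglik_tensor
from .types import PhyloTree, ReadSets

__all__ = [
    "Partition",
    "ConfigTree",
    "PartitionGraphs",
    "haplotype_mixture_em",
    "partition_pphs2",
    "enumerate_config_trees",
    "subtree_em",
    "tree_log_likelihood",
    "tree_likelihood",
    "build_partition_graphs",
    "best_partition",
    "reconstruct_tree",
    "initial_frequencies",
]

_FREQ_CLAMP = 1e-6


@dataclass(frozen=True)
class Partition:
    """Split of a window's SNPs around the root SNP j*."""

    t1: frozenset[int]  # side subtree: not descendants of j*
    t2: frozenset[int]  # below j*

    def __post_init__(self) -> None:
        if self.t1 & self.t2:
            raise ValueError("partition sides must be disjoint")


@dataclass(frozen=True)
class ConfigTree:
    """A three-SNP subtree hypothesis tagged by its (a, b) side configuration."""

    tree: PhyloTree
    config: tuple[int, int]


@dataclass
class PartitionGraphs:
    """The four pairwise-configuration weight graphs used by PPHS-3.

    ``w11``/``w22`` are symmetric; ``w12[x, y]`` is the weight of
    (x in T1, y in T2) and doubles as w21[y, x]. Weights are mean subtree
    likelihoods normalized per pair by that pair's best topology, so every
    pair's configuration evidence lives on a comparable (0, 1] scale:
    unnormalized likelihood magnitudes differ across site triples by many
    orders of magnitude and would let a single pair dominate the sum.
    """

    snps: list[int]
    w11: np.ndarray
    w22: np.ndarray
    w12: np.ndarray


# ---------------------------------------------------------------------------
# haplotype-frequency mixture EM
# ---------------------------------------------------------------------------


def haplotype_mixture_em(
    loglik: np.ndarray,
    p0: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> tuple[np.ndarray, float, int]:
    """EM for haplotype frequencies in the unordered-pair mixture.

    ``loglik[i, a, b]`` is log Pr(R_i | h_a, h_b); individuals are mixtures
    over ordered pairs drawn p_a * p_b. Returns (p, final log-likelihood,
    iterations). The likelihood is non-decreasing across iterations.
    """
    n, K, _ = loglik.shape
    p = np.asarray(p0, dtype=float)
    p = p / p.sum()
    if n == 0:
        return p, 0.0, 0

    def full_ll(p: np.ndarray) -> tuple[float, np.ndarray]:
        with np.errstate(divide="ignore"):
            lp = np.log(p)
        w = loglik + lp[None, :, None] + lp[None, None, :]
        flat = w.reshape(n, K * K)
        mx = flat.max(axis=1)
        mx_safe = np.where(np.isfinite(mx), mx, 0.0)
        z = np.exp(flat - mx_safe[:, None]).sum(axis=1)
        ll = float((mx_safe + np.log(z)).sum())
        q = np.exp(flat - mx_safe[:, None]) / z[:, None]
        return ll, q.reshape(n, K, K)

    prev, q = full_ll(p)
    iters = 0
    for iters in range(1, max_iter + 1):
        counts = q.sum(axis=2).sum(axis=0) + q.sum(axis=1).sum(axis=0)
        p_new = counts / (2 * n)
        cur, q_new = full_ll(p_new)
        if cur < prev - 1e-9:
            break
        p, q = p_new, q_new
        if cur - prev < tol:
            prev = cur
            break
        prev = cur
    return p, prev, iters


# ---------------------------------------------------------------------------
# frequency initialization from per-SNP allele frequencies
# ---------------------------------------------------------------------------


def initial_frequencies(tree: PhyloTree, freqs: Mapping[int, float]) -> np.ndarray:
    """Node frequencies implied by per-SNP allele frequencies.

    p_v = f(parent edge of v) - sum of f over v's child edges, with f = 1
    for the root's virtual parent. Exact when the allele frequencies are
    exact; may go negative under noise, so entries are clamped at 1e-6 and
    renormalized. An all-non-positive vector falls back to uniform.
    """
    raw = np.empty(tree.n_nodes)
    for v in range(tree.n_nodes):
        top = 1.0 if tree.edge_snps[v] is None else freqs[tree.edge_snps[v]]
        below = sum(freqs[tree.edge_snps[c]] for c in tree.children(v))
        raw[v] = top - below
    if np.all(raw <= 0):
        return np.full(tree.n_nodes, 1.0 / tree.n_nodes)
    clamped = np.maximum(raw, _FREQ_CLAMP)
    return clamped / clamped.sum()


# ---------------------------------------------------------------------------
# PPHS-2: independent per-SNP partitioning
# ---------------------------------------------------------------------------

# minimal perfect-phylogeny models over the site pair (j*, j)
_T1_MODEL = np.array([[0, 0], [1, 0], [0, 1]])  # j beside j*: no 11 haplotype
_T2_MODEL = np.array([[0, 0], [1, 0], [1, 1]])  # j below j*: no 01 haplotype


def _pphs2_inits(f_star: float, f_j: float) -> tuple[np.ndarray, np.ndarray]:
    p1 = np.array([1.0 - f_star - f_j, f_star, f_j])
    p2 = np.array([1.0 - f_star, f_star - f_j, f_j])

    def fix(p: np.ndarray) -> np.ndarray:
        if np.all(p <= 0):
            return np.full(p.shape, 1.0 / p.size)
        p = np.maximum(p, _FREQ_CLAMP)
        return p / p.sum()

    return fix(p1), fix(p2)


def partition_pphs2(
    jstar: int,
    snps: Sequence[int],
    reads: ReadSets,
    eps: float,
    freqs: Mapping[int, float] | None = None,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> Partition:
    """Assign each SNP to T1 or T2 by its own two-SNP likelihood contest.

    For SNP j the reads restricted to {j*, j} are scored under the two
    minimal perfect-phylogeny models: {00, 10, 01} (j on the side of the
    root) and {00, 10, 11} (j below j*), each with frequencies maximized by
    EM. Ties go to T1.
    """
    if jstar in snps:
        raise ValueError("j* must not be in the SNP set to partition")
    t1, t2 = set(), set()
    for j in snps:
        if freqs is not None:
            p1_0, p2_0 = _pphs2_inits(freqs[jstar], freqs[j])
        else:
            p1_0 = p2_0 = np.full(3, 1.0 / 3)
        L1 = pair_loglik_tensor(reads, [jstar, j], _T1_MODEL, eps)
        L2 = pair_loglik_tensor(reads, [jstar, j], _T2_MODEL, eps)
        _, ll1, _ = haplotype_mixture_em(L1, p1_0, tol, max_iter)
        _, ll2, _ = haplotype_mixture_em(L2, p2_0, tol, max_iter)
        # tie margin sits above the EM convergence residual (tol in ll units)
        (t2 if ll2 > ll1 + 10 * tol else t1).add(j)
    return Partition(frozenset(t1), frozenset(t2))


# ---------------------------------------------------------------------------
# PPHS-3: pairwise-configuration graphs
# ---------------------------------------------------------------------------


def enumerate_config_trees(
    jstar: int, j1: int, j2: int, config: tuple[int, int]
) -> list[ConfigTree]:
    """All three-SNP subtrees consistent with placing (j1, j2) on sides (a, b).

    Configurations (1,1) and (2,2) admit three topologies (siblings, j2
    under j1, j1 under j2); the mixed configurations admit exactly one.
    """
    if len({jstar, j1, j2}) != 3:
        raise ValueError("j*, j1, j2 must be distinct")
    if config not in {(1, 1), (2, 2), (1, 2), (2, 1)}:
        raise ValueError(f"invalid configuration {config!r}")
    snps = [jstar, j1, j2]

    def tree(parents: list[int | None], edges: list[int | None]) -> PhyloTree:
        return PhyloTree(snps=snps, parents=parents, edge_snps=edges)

    if config == (1, 1):
        shapes = [
            tree([None, 0, 0, 0], [None, jstar, j1, j2]),  # siblings at the root
            tree([None, 0, 0, 2], [None, jstar, j1, j2]),  # j2 under j1
            tree([None, 0, 0, 2], [None, jstar, j2, j1]),  # j1 under j2
        ]
    elif config == (2, 2):
        shapes = [
            tree([None, 0, 1, 1], [None, jstar, j1, j2]),  # siblings under j*
            tree([None, 0, 1, 2], [None, jstar, j1, j2]),  # j* -> j1 -> j2
            tree([None, 0, 1, 2], [None, jstar, j2, j1]),  # j* -> j2 -> j1
        ]
    elif config == (1, 2):
        shapes = [tree([None, 0, 0, 1], [None, jstar, j1, j2])]  # j1 at root, j2 under j*
    else:  # (2, 1)
        shapes = [tree([None, 0, 1, 0], [None, jstar, j1, j2])]  # j1 under j*, j2 at root
    return [ConfigTree(t, config) for t in shapes]


def subtree_em(
    topology: ConfigTree | PhyloTree,
    reads: ReadSets,
    eps: float,
    freqs: Mapping[int, float],
    tol: float = 1e-6,
    max_iter: int = 200,
) -> tuple[PhyloTree, float]:
    """Fit node frequencies of one subtree hypothesis by mixture EM.

    Initialized from the per-SNP allele frequencies via the parent-minus-
    children formula; returns the fitted tree and its final log-likelihood
    over reads restricted to the subtree's SNPs.
    """
    tree = topology.tree if isinstance(topology, ConfigTree) else topology
    p0 = initial_frequencies(tree, freqs)
    haps = np.asarray(tree.haplotypes())
    L = pair_loglik_tensor(reads, tree.snps, haps, eps)
    p, ll, _ = haplotype_mixture_em(L, p0, tol, max_iter)
    fitted = PhyloTree(
        snps=list(tree.snps),
        parents=list(tree.parents),
        edge_snps=list(tree.edge_snps),
        frequencies=p,
    )
    return fitted, ll


def tree_log_likelihood(tree: PhyloTree, reads: ReadSets, eps: float) -> float:
    """log Pr(R | T): product over individuals of the pair-mixture likelihood."""
    if tree.frequencies is None:
        raise ValueError("tree has no frequencies")
    haps = np.asarray(tree.haplotypes())
    L = pair_loglik_tensor(reads, tree.snps, haps, eps)
    with np.errstate(divide="ignore"):
        lp = np.log(tree.frequencies)
    w = L + lp[None, :, None] + lp[None, None, :]
    flat = w.reshape(w.shape[0], -1)
    mx = flat.max(axis=1)
    mx = np.where(np.isfinite(mx), mx, 0.0)
    return float((mx + np.log(np.exp(flat - mx[:, None]).sum(axis=1))).sum())


def tree_likelihood(tree: PhyloTree, reads: ReadSets, eps: float) -> float:
    """Pr(R | T) on the probability scale (may underflow for large cohorts)."""
    return float(np.exp(tree_log_likelihood(tree, reads, eps)))


def build_partition_graphs(
    jstar: int,
    snps: Sequence[int],
    reads: ReadSets,
    eps: float,
    freqs: Mapping[int, float],
    tol: float = 1e-6,
    max_iter: int = 200,
) -> PartitionGraphs:
    """Fit every pairwise subtree hypothesis and build the four weight graphs.

    For each unordered SNP pair and configuration, the weight is the mean of
    Pr(R | T*) over that configuration's topologies (3 for same-side, 1 for
    mixed), each fitted by subtree_em, divided by the pair's maximum
    topology likelihood (a per-pair constant; see PartitionGraphs).
    """
    nodes = sorted(snps)
    if len(nodes) < 2:
        raise ValueError("need at least two SNPs besides j*")
    K = len(nodes)
    idx = {j: k for k, j in enumerate(nodes)}
    logw = {
        (1, 1): np.full((K, K), -np.inf),
        (2, 2): np.full((K, K), -np.inf),
        (1, 2): np.full((K, K), -np.inf),
    }

    def log_mean(values: list[float]) -> float:
        arr = np.asarray(values)
        mx = arr.max()
        if not np.isfinite(mx):
            return -np.inf
        return float(mx + np.log(np.exp(arr - mx).mean()))

    shifts = np.zeros((K, K))
    for x, y in combinations(nodes, 2):
        pair_best = -np.inf
        for config in [(1, 1), (2, 2), (1, 2), (2, 1)]:
            lls = []
            for hyp in enumerate_config_trees(jstar, x, y, config):
                _, ll = subtree_em(hyp, reads, eps, freqs, tol, max_iter)
                lls.append(ll)
                pair_best = max(pair_best, ll)
            val = log_mean(lls)
            a, b = idx[x], idx[y]
            if config == (1, 1):
                logw[(1, 1)][a, b] = logw[(1, 1)][b, a] = val
            elif config == (2, 2):
                logw[(2, 2)][a, b] = logw[(2, 2)][b, a] = val
            elif config == (1, 2):
                logw[(1, 2)][a, b] = val
            else:  # (2, 1) for (x, y) is (x in T2, y in T1) == w12[y, x]
                logw[(1, 2)][b, a] = val
        a, b = idx[x], idx[y]
        shifts[a, b] = shifts[b, a] = pair_best if np.isfinite(pair_best) else 0.0

    weights = {}
    for key, arr in logw.items():
        w = np.exp(arr - shifts)
        np.fill_diagonal(w, 0.0)
        weights[key] = w
    return PartitionGraphs(nodes, weights[(1, 1)], weights[(2, 2)], weights[(1, 2)])


def _partition_objective(graphs: PartitionGraphs, in_t1: np.ndarray) -> float:
    s = in_t1.astype(float)
    t = 1.0 - s
    return float(s @ graphs.w11 @ s + t @ graphs.w22 @ t + 2.0 * (s @ graphs.w12 @ t))


def _exact_partition(graphs: PartitionGraphs) -> np.ndarray:
    K = len(graphs.snps)
    best_mask, best_val = 0, -np.inf
    for mask in range(2**K):
        # bit set -> SNP in T2, so mask 0 (all T1) wins flat objectives
        in_t1 = np.array([(mask >> k) & 1 == 0 for k in range(K)])
        val = _partition_objective(graphs, in_t1)
        if val > best_val + 1e-12:
            best_val, best_mask = val, mask
    return np.array([(best_mask >> k) & 1 == 0 for k in range(K)])


def best_partition(
    graphs: PartitionGraphs,
    rng: np.random.Generator | None = None,
    max_enumeration: int = 12,
    subset_size: int = 10,
) -> Partition:
    """Maximize the summed configuration-consistent weights over partitions.

    Exact enumeration of all 2^K assignments for K <= max_enumeration;
    otherwise random subsets of ``subset_size`` SNPs are solved exactly and
    each SNP's side is decided by majority vote over the subsets containing
    it (ties to T1).
    """
    K = len(graphs.snps)
    if K <= max_enumeration:
        in_t1 = _exact_partition(graphs)
    else:
        if rng is None:
            rng = np.random.default_rng(0)
        n_subsets = subset_size * int(np.ceil(K / subset_size)) * 5
        votes_t1 = np.zeros(K)
        votes_t2 = np.zeros(K)
        for _ in range(n_subsets):
            members = rng.choice(K, size=subset_size, replace=False)
            sub = PartitionGraphs(
                [graphs.snps[k] for k in members],
                graphs.w11[np.ix_(members, members)],
                graphs.w22[np.ix_(members, members)],
                graphs.w12[np.ix_(members, members)],
            )
            sub_t1 = _exact_partition(sub)
            votes_t1[members[sub_t1]] += 1
            votes_t2[members[~sub_t1]] += 1
        in_t1 = votes_t1 >= votes_t2
    t1 = {graphs.snps[k] for k in range(K) if in_t1[k]}
    t2 = {graphs.snps[k] for k in range(K) if not in_t1[k]}
    return Partition(frozenset(t1), frozenset(t2))


# ---------------------------------------------------------------------------
# full recursive reconstruction
# ---------------------------------------------------------------------------


def reconstruct_tree(
    reads: ReadSets,
    snps: Sequence[int],
    eps: float,
    method: str = "pphs2",
    rng: np.random.Generator | None = None,
    max_window: int = 50,
    max_enumeration: int = 12,
    estimates: Mapping[int, AlleleFreqEstimate] | None = None,
) -> PhyloTree:
    """Reconstruct the window's perfect-phylogeny tree from reads.

    Recursion: pick j* by largest estimated allele frequency, partition the
    remaining SNPs (PPHS-2 or PPHS-3), hang the T1 subtree at the current
    root and the T2 subtree below the j* edge. Node frequencies of the
    final topology come from the parent-minus-children formula applied to
    the per-SNP EM frequency estimates.
    """
    snps = list(snps)
    if not 1 <= len(snps) <= max_window:
        raise ValueError(f"window must contain 1..{max_window} SNPs")
    if method not in ("pphs2", "pphs3"):
        raise ValueError(f"unknown method {method!r}")
    if rng is None:
        rng = np.random.default_rng(0)

    if estimates is None:
        estimates = estimate_frequencies(reads, snps, eps)
    freqs = {j: estimates[j].frequency for j in snps}

    def _build(active: list[int]) -> dict:
        if not active:
            return {}
        jstar = select_root_snp([estimates[j] for j in active])
        rest = [j for j in active if j != jstar]
        if not rest:
            part = Partition(frozenset(), frozenset())
        elif method == "pphs2" or len(rest) < 2:
            part = partition_pphs2(jstar, rest, reads, eps, freqs)
        else:
            graphs = build_partition_graphs(jstar, rest, reads, eps, freqs)
            part = best_partition(graphs, rng, max_enumeration=max_enumeration)
        side = _build(sorted(part.t1))
        below = _build(sorted(part.t2))
        return {**side, jstar: below}

    nested = _build(snps)

    parents: list[int | None] = [None]
    edge_snps: list[int | None] = [None]

    def flatten(children: dict, parent: int) -> None:
        for snp in sorted(children):
            parents.append(parent)
            edge_snps.append(snp)
            flatten(children[snp], len(parents) - 1)

    flatten(nested, 0)
    tree = PhyloTree(snps=snps, parents=parents, edge_snps=edge_snps)
    tree.frequencies = initial_frequencies(tree, freqs)
    tree.validate()
    return tree


def estimate_frequencies(
    reads: ReadSets, snps: Sequence[int], eps: float
) -> dict[int, AlleleFreqEstimate]:
    """Per-SNP EM allele-frequency estimates with naive-count initialization."""
    logA = genotype_loglik_table(reads, max(eps, 1e-12))
    out = {}
    for j in snps:
        init = naive_frequency_init(reads.alleles[:, j])
        out[j] = em_allele_frequency(logA[:, j, :], snp_index=j, init=init, log=True)
    return out
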