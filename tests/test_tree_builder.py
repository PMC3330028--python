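"""Tree reconstruction: partitioning, subtree EM, likelihoods, recursion."""

import itertools

import numpy as np
import pytest

from pphs.read_model import read_pair_likelihood
from pphs.simulate import sample_individuals, simulate_readsets, simulate_tree, tree_allele_frequencies
from pphs.tree_builder import (
    Partition,
    PartitionGraphs,
    best_partition,
    build_partition_graphs,
    enumerate_config_trees,
    haplotype_mixture_em,
    initial_frequencies,
    partition_pphs2,
    reconstruct_tree,
    subtree_em,
    tree_likelihood,
    tree_log_likelihood,
)
from pphs.types import HaplotypePair, PhyloTree, Read, ReadSets, SimulationParams
from tests.conftest import reads_from_haplotype_pairs


def _pairs_from_hap_freqs(haps, freqs, n, rng):
    idx = rng.choice(len(haps), size=(n, 2), p=freqs)
    return [HaplotypePair(f"i{k}", haps[idx[k, 0]], haps[idx[k, 1]]) for k in range(n)]


# ---------------------------------------------------------------------------
# PPHS-2
# ---------------------------------------------------------------------------


def test_pphs2_places_descendant_snp_below_jstar(rng):
    """Haplotypes {00, 10, 11} over (j*, j): the 11 gamete forces j in T2."""
    pairs = _pairs_from_hap_freqs(
        [(0, 0), (1, 0), (1, 1)], [0.4, 0.3, 0.3], 60, rng
    )
    reads = reads_from_haplotype_pairs(pairs)
    part = partition_pphs2(0, [1], reads, 0.0)
    assert part.t2 == {1}


def test_pphs2_places_sibling_snp_beside_jstar(rng):
    """Haplotypes {00, 10, 01}: the 01 gamete keeps j in T1."""
    pairs = _pairs_from_hap_freqs(
        [(0, 0), (1, 0), (0, 1)], [0.4, 0.3, 0.3], 60, rng
    )
    reads = reads_from_haplotype_pairs(pairs)
    part = partition_pphs2(0, [1], reads, 0.0)
    assert part.t1 == {1}


def test_pphs2_tie_goes_to_t1():
    """No read covers SNP 1: both models reach the same maximum."""
    reads = ReadSets.from_reads([Read("a", "r", ((0, 1),))], 2)
    part = partition_pphs2(0, [1], reads, 0.05)
    assert part.t1 == {1}


def test_pphs2_agrees_with_exhaustive_two_snp_likelihoods(rng):
    """The winning side equals a dense grid maximization of both models."""
    pairs = _pairs_from_hap_freqs([(0, 0), (1, 0), (1, 1)], [0.5, 0.2, 0.3], 40, rng)
    reads = reads_from_haplotype_pairs(pairs)
    eps = 0.01

    def model_max(haps):
        best = -np.inf
        grid = np.linspace(0.01, 0.98, 25)
        for p1 in grid:
            for p2 in grid:
                if p1 + p2 >= 0.995:
                    continue
                p = np.array([1 - p1 - p2, p1, p2])
                ll = 0.0
                for i, name in enumerate(reads.individuals):
                    rs = [r for r in reads.to_reads() if r.individual_id == name]
                    tot = 0.0
                    for a in range(3):
                        for b in range(3):
                            lik = 1.0
                            for r in rs:
                                lik *= read_pair_likelihood(
                                    r, HaplotypePair(name, haps[a], haps[b]), eps
                                )
                            tot += p[a] * p[b] * lik
                    ll += np.log(tot)
                best = max(best, ll)
        return best

    ll_t1 = model_max([(0, 0), (1, 0), (0, 1)])
    ll_t2 = model_max([(0, 0), (1, 0), (1, 1)])
    part = partition_pphs2(0, [1], reads, eps)
    expected = {1} if ll_t2 > ll_t1 else set()
    assert set(part.t2) == expected


# ---------------------------------------------------------------------------
# configuration subtrees and their EM
# ---------------------------------------------------------------------------


def test_configuration_topology_counts():
    assert len(enumerate_config_trees(0, 1, 2, (1, 1))) == 3
    assert len(enumerate_config_trees(0, 1, 2, (2, 2))) == 3
    assert len(enumerate_config_trees(0, 1, 2, (1, 2))) == 1
    assert len(enumerate_config_trees(0, 1, 2, (2, 1))) == 1
    total = sum(
        len(enumerate_config_trees(0, 1, 2, c))
        for c in [(1, 1), (2, 2), (1, 2), (2, 1)]
    )
    assert total == 8
    for c in [(1, 1), (2, 2), (1, 2), (2, 1)]:
        for hyp in enumerate_config_trees(0, 1, 2, c):
            hyp.tree.validate()
    with pytest.raises(ValueError):
        enumerate_config_trees(0, 1, 2, (3, 1))


def test_mixed_configurations_respect_sides():
    """(1,2): j1 beside the root, j2 below j*; (2,1) mirrored."""
    [hyp] = enumerate_config_trees(0, 1, 2, (1, 2))
    haps = hyp.tree.haplotype_set()  # columns (j*, j1, j2)
    assert (0, 1, 0) in haps and (1, 0, 1) in haps
    [hyp] = enumerate_config_trees(0, 1, 2, (2, 1))
    haps = hyp.tree.haplotype_set()
    assert (1, 1, 0) in haps and (0, 0, 1) in haps


def test_subtree_em_without_reads_keeps_initialization():
    [hyp] = enumerate_config_trees(0, 1, 2, (1, 2))
    empty = ReadSets(["a"], 3, np.full((0, 3), -1, np.int8), np.empty(0, np.int64))
    freqs = {0: 0.3, 1: 0.2, 2: 0.1}
    fitted, _ = subtree_em(hyp, empty, 0.02, freqs)
    assert np.allclose(fitted.frequencies, initial_frequencies(hyp.tree, freqs))


def test_subtree_em_fixed_point_at_exact_frequencies(rng):
    """Exact allele frequencies on the true topology are (near) stationary."""
    hyp = enumerate_config_trees(0, 1, 2, (2, 2))[1]  # chain j* -> j1 -> j2
    tree = hyp.tree
    p_true = np.array([0.4, 0.25, 0.2, 0.15])
    haps = tree.haplotypes()
    pairs = _pairs_from_hap_freqs(haps, p_true, 4000, rng)
    reads = reads_from_haplotype_pairs(pairs)
    # tree-implied exact allele frequencies per SNP column
    f = {}
    for k, snp in enumerate(tree.snps):
        f[snp] = sum(float(p_true[u]) for u in range(4) if haps[u][k] == 1)
    p0 = initial_frequencies(tree, f)
    assert np.allclose(p0, p_true, atol=1e-9)
    fitted, _ = subtree_em(hyp, reads, 0.0, f)
    assert np.allclose(fitted.frequencies, p_true, atol=0.03)


def test_mixture_em_likelihood_non_decreasing(rng):
    K, n = 4, 30
    L = rng.normal(-5, 2, size=(n, K, K))
    L = (L + L.transpose(0, 2, 1)) / 2
    p0 = np.full(K, 0.25)
    lls = []
    for iters in range(1, 15):
        _, ll, _ = haplotype_mixture_em(L, p0, tol=0.0, max_iter=iters)
        lls.append(ll)
    assert all(b >= a - 1e-9 for a, b in zip(lls, lls[1:]))


def test_mixture_em_matches_simplex_grid_search(rng):
    """Small instance: EM optimum matches a dense simplex grid."""
    K, n = 3, 25
    L = rng.normal(-3, 1.5, size=(n, K, K))
    L = (L + L.transpose(0, 2, 1)) / 2
    _, ll_em, _ = haplotype_mixture_em(L, np.full(K, 1 / 3))

    best = -np.inf
    step = 0.02
    for a in np.arange(step, 1, step):
        for b in np.arange(step, 1 - a, step):
            p = np.array([a, b, 1 - a - b])
            w = L + np.log(p)[None, :, None] + np.log(p)[None, None, :]
            flat = w.reshape(n, -1)
            mx = flat.max(axis=1)
            best = max(best, float((mx + np.log(np.exp(flat - mx[:, None]).sum(1))).sum()))
    assert ll_em >= best - 0.05


# ---------------------------------------------------------------------------
# tree likelihood
# ---------------------------------------------------------------------------


def test_tree_likelihood_matches_brute_force(rng):
    [hyp] = enumerate_config_trees(0, 1, 2, (1, 2))
    tree = hyp.tree
    tree.frequencies = np.array([0.4, 0.3, 0.2, 0.1])
    haps = tree.haplotypes()
    reads = [
        Read("a", "r1", ((0, 1), (2, 1))),
        Read("a", "r2", ((1, 0),)),
        Read("b", "r3", ((0, 0), (1, 1), (2, 0))),
        Read("c", "r4", ((2, 1),)),
    ]
    rs = ReadSets.from_reads(reads, 3)
    eps = 0.05
    direct = 1.0
    for name in rs.individuals:
        tot = 0.0
        for a in range(4):
            for b in range(4):
                lik = 1.0
                for r in reads:
                    if r.individual_id == name:
                        lik *= read_pair_likelihood(r, HaplotypePair(name, haps[a], haps[b]), eps)
                tot += tree.frequencies[a] * tree.frequencies[b] * lik
        direct *= tot
    assert tree_likelihood(tree, rs, eps) == pytest.approx(direct, rel=1e-10)


def test_tree_likelihood_no_reads_is_one():
    [hyp] = enumerate_config_trees(0, 1, 2, (1, 2))
    hyp.tree.frequencies = np.array([0.4, 0.3, 0.2, 0.1])
    empty = ReadSets(["a"], 3, np.full((0, 3), -1, np.int8), np.empty(0, np.int64))
    assert tree_likelihood(hyp.tree, empty, 0.02) == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# PPHS-3 graphs and partitioning
# ---------------------------------------------------------------------------


def _random_graphs(m, rng):
    w11 = rng.random((m, m))
    w11 = (w11 + w11.T) / 2
    w22 = rng.random((m, m))
    w22 = (w22 + w22.T) / 2
    w12 = rng.random((m, m))
    for w in (w11, w22, w12):
        np.fill_diagonal(w, 0.0)
    return PartitionGraphs(list(range(m)), w11, w22, w12)


def _oracle_best(graphs):
    """Brute force over all ordered partitions, straight from the definition."""
    m = len(graphs.snps)
    best_val, best_sets = -np.inf, None
    for bits in itertools.product([0, 1], repeat=m):
        val = 0.0
        for x in range(m):
            for y in range(m):
                if x == y:
                    continue
                if bits[x] == 0 and bits[y] == 0:
                    val += graphs.w11[x, y]
                elif bits[x] == 1 and bits[y] == 1:
                    val += graphs.w22[x, y]
                elif bits[x] == 0 and bits[y] == 1:
                    val += graphs.w12[x, y]
                else:
                    val += graphs.w12[y, x]
        if val > best_val + 1e-12:
            best_val = val
            best_sets = bits
    t1 = frozenset(j for j in range(m) if best_sets[j] == 0)
    t2 = frozenset(j for j in range(m) if best_sets[j] == 1)
    return Partition(t1, t2), best_val


@pytest.mark.parametrize("m", [2, 4, 6, 8])
def test_exact_partition_matches_brute_force(m, rng):
    for _ in range(8):
        graphs = _random_graphs(m, rng)
        got = best_partition(graphs)
        oracle, _ = _oracle_best(graphs)
        assert got == oracle


def test_flat_weights_give_all_t1():
    m = 5
    ones = np.ones((m, m))
    np.fill_diagonal(ones, 0.0)
    graphs = PartitionGraphs(list(range(m)), ones.copy(), ones.copy(), ones.copy())
    part = best_partition(graphs)
    assert part.t1 == frozenset(range(m)) and not part.t2


def test_subset_voting_recovers_strong_structure(rng):
    """Majority vote on a >12-SNP instance with a dominant split."""
    m = 15
    t2_true = set(range(5))
    w11 = np.full((m, m), 0.1)
    w22 = np.full((m, m), 0.1)
    w12 = np.full((m, m), 0.1)
    for x in range(m):
        for y in range(m):
            if x == y:
                continue
            in1x, in1y = x not in t2_true, y not in t2_true
            if in1x and in1y:
                w11[x, y] = 1.0
            elif not in1x and not in1y:
                w22[x, y] = 1.0
            elif in1x and not in1y:
                w12[x, y] = 1.0
    for w in (w11, w22, w12):
        np.fill_diagonal(w, 0.0)
    graphs = PartitionGraphs(list(range(m)), w11, w22, w12)
    part = best_partition(graphs, rng=np.random.default_rng(3), max_enumeration=12)
    assert part.t2 == frozenset(t2_true)


def test_partition_graph_weights_structure(rng):
    tree = simulate_tree(4, 0.1, rng)
    pairs = sample_individuals(tree, 40, rng)
    reads = reads_from_haplotype_pairs(pairs)
    from pphs.tree_builder import estimate_frequencies

    est = estimate_frequencies(reads, range(4), 0.01)
    freqs = {j: est[j].frequency for j in range(4)}
    jstar = max(freqs, key=freqs.get)
    rest = [j for j in range(4) if j != jstar]
    graphs = build_partition_graphs(jstar, rest, reads, 0.01, freqs)
    assert graphs.snps == sorted(rest)
    K = len(rest)
    assert graphs.w11.shape == (K, K)
    assert np.allclose(graphs.w11, graphs.w11.T)
    assert np.allclose(graphs.w22, graphs.w22.T)
    assert np.all(graphs.w11 >= 0) and np.all(np.isfinite(graphs.w12))


def test_pphs3_identifies_true_configuration_noiselessly(rng):
    """Chain tree j* -> j1 -> j2: config (2,2) must outweigh the others."""
    hyp = enumerate_config_trees(0, 1, 2, (2, 2))[1]  # j2 under j1 under j*
    tree = hyp.tree
    p_true = np.array([0.4, 0.25, 0.2, 0.15])
    pairs = _pairs_from_hap_freqs(tree.haplotypes(), p_true, 200, rng)
    reads = reads_from_haplotype_pairs(pairs)
    haps = tree.haplotypes()
    f = {snp: sum(float(p_true[u]) for u in range(4) if haps[u][k] == 1)
         for k, snp in enumerate(tree.snps)}
    scores = {}
    for config in [(1, 1), (2, 2), (1, 2), (2, 1)]:
        lls = [
            subtree_em(h, reads, 0.001, f)[1]
            for h in enumerate_config_trees(0, 1, 2, config)
        ]
        scores[config] = max(lls)
    assert max(scores, key=scores.get) == (2, 2)


# ---------------------------------------------------------------------------
# full recursion
# ---------------------------------------------------------------------------


def test_single_snp_window():
    reads = ReadSets.from_reads([Read("a", "r", ((0, 1),))], 1)
    tree = reconstruct_tree(reads, [0], 0.02)
    tree.validate()
    assert tree.n_nodes == 2
    assert tree.haplotype_set() == {(0,), (1,)}


def test_window_size_limit_enforced():
    reads = ReadSets.from_reads([Read("a", "r", ((0, 1),))], 60)
    with pytest.raises(ValueError):
        reconstruct_tree(reads, range(60), 0.02, max_window=50)


def test_noiseless_reconstruction_recovers_haplotype_set():
    for seed in range(5):
        rng = np.random.default_rng(seed)
        params = SimulationParams(
            n_individuals=200, m_snps=8, coverage_k=30, read_length_l=9000,
            error_rate=0.0, region_length=9000, min_hap_freq=0.05, seed=seed,
        )
        tree = simulate_tree(8, 0.05, rng)
        pairs = sample_individuals(tree, 200, rng)
        reads = simulate_readsets(pairs, params, rng)
        rec = reconstruct_tree(reads, range(8), 0.0, method="pphs2")
        rec.validate()
        assert rec.haplotype_set() == tree.haplotype_set()


def test_pphs2_and_pphs3_agree_on_clean_separated_data():
    agree = 0
    trials = 10
    for seed in range(trials):
        rng = np.random.default_rng(100 + seed)
        tree = simulate_tree(5, 0.08, rng)
        pairs = sample_individuals(tree, 150, rng)
        reads = reads_from_haplotype_pairs(pairs)
        r2 = reconstruct_tree(reads, range(5), 0.0, method="pphs2")
        r3 = reconstruct_tree(reads, range(5), 0.0, method="pphs3", rng=rng)
        agree += r2.haplotype_set() == r3.haplotype_set()
    assert agree >= trials - 1


def test_reconstructed_tree_is_always_valid(rng):
    for seed in range(5):
        params = SimulationParams(
            n_individuals=10, m_snps=6, coverage_k=4, read_length_l=300,
            error_rate=0.05, region_length=7000, seed=seed,
        )
        local = np.random.default_rng(seed)
        tree = simulate_tree(6, 0.05, local)
        pairs = sample_individuals(tree, 10, local)
        reads = simulate_readsets(pairs, params, local)
        rec = reconstruct_tree(reads, range(6), 0.05, method="pphs2")
        rec.validate()
        assert abs(rec.frequencies.sum() - 1) < 1e-9
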