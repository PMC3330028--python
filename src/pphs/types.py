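"""Core containers: haplotypes, reads, perfect-phylogeny trees.

A haplotype over a window of ``m`` biallelic SNPs is a binary vector; the
window is indexed 0-based. Reads are site-restricted: only the alleles
observed at window SNPs are kept, everything between SNPs is irrelevant to
phasing. A perfect-phylogeny tree has one edge per SNP (each SNP mutates
exactly once, 0 -> 1, and never back), so a window of ``m`` SNPs yields a
tree with exactly ``m + 1`` nodes, each node a distinct haplotype carrying
a population frequency ``p_v``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Read",
    "HaplotypePair",
    "ReadSets",
    "PhyloTree",
    "SimulationParams",
]


@dataclass(frozen=True)
class Read:
    """One sequencing read restricted to window SNPs.

    ``observations`` is an ordered list of ``(site_index, allele)`` with
    strictly increasing 0-based site indices and alleles in {0, 1}.
    """

    individual_id: str
    read_id: str
    observations: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        obs = tuple((int(s), int(a)) for s, a in self.observations)
        object.__setattr__(self, "observations", obs)
        if not obs:
            raise ValueError("a read must observe at least one site")
        sites = [s for s, _ in obs]
        if any(b <= a for a, b in zip(sites, sites[1:])):
            raise ValueError("read site indices must be strictly increasing")
        if any(s < 0 for s in sites):
            raise ValueError("read site indices must be non-negative")
        if any(a not in (0, 1) for _, a in obs):
            raise ValueError("read alleles must be 0 or 1")

    @property
    def sites(self) -> tuple[int, ...]:
        return tuple(s for s, _ in self.observations)

    @property
    def alleles(self) -> tuple[int, ...]:
        return tuple(a for _, a in self.observations)


@dataclass(frozen=True)
class HaplotypePair:
    """The two haplotypes of one diploid individual over a window."""

    individual_id: str
    h1: tuple[int, ...]
    h2: tuple[int, ...]

    def __post_init__(self) -> None:
        h1 = tuple(int(x) for x in self.h1)
        h2 = tuple(int(x) for x in self.h2)
        if len(h1) != len(h2):
            raise ValueError("haplotypes of a pair must have equal length")
        if any(x not in (0, 1) for x in h1 + h2):
            raise ValueError("haplotype alleles must be 0 or 1")
        object.__setattr__(self, "h1", h1)
        object.__setattr__(self, "h2", h2)

    def __len__(self) -> int:
        return len(self.h1)

    def genotypes(self) -> tuple[int, ...]:
        """Per-site genotype g = h1 + h2 in {0, 1, 2}."""
        return tuple(a + b for a, b in zip(self.h1, self.h2))

    def swapped(self) -> "HaplotypePair":
        return HaplotypePair(self.individual_id, self.h2, self.h1)

    def slice(self, start: int, stop: int) -> "HaplotypePair":
        return HaplotypePair(self.individual_id, self.h1[start:stop], self.h2[start:stop])


class ReadSets:
    """Per-individual collections of site-restricted reads for a cohort.

    Internally the observations are held as a dense ``(n_reads, m)`` int8
    matrix with -1 for sites a read does not cover, plus a read-to-individual
    index; this is the representation every likelihood routine works on.
    """

    def __init__(
        self,
        individuals: Sequence[str],
        m_snps: int,
        alleles: np.ndarray,
        read_individual: np.ndarray,
        read_ids: Sequence[str] | None = None,
    ) -> None:
        self.individuals = list(individuals)
        self.m = int(m_snps)
        self.alleles = np.asarray(alleles, dtype=np.int8)
        self.read_individual = np.asarray(read_individual, dtype=np.int64)
        if self.alleles.ndim != 2 or self.alleles.shape[1] != self.m:
            raise ValueError("allele matrix shape does not match m_snps")
        if self.alleles.shape[0] != self.read_individual.shape[0]:
            raise ValueError("read_individual length does not match allele matrix")
        if read_ids is not None and len(read_ids) != self.alleles.shape[0]:
            raise ValueError("read_ids length does not match allele matrix")
        self.read_ids = list(read_ids) if read_ids is not None else None

    # -- constructors -------------------------------------------------

    @classmethod
    def from_reads(
        cls,
        reads: Iterable[Read],
        m_snps: int,
        individuals: Sequence[str] | None = None,
    ) -> "ReadSets":
        reads = list(reads)
        if individuals is None:
            seen: dict[str, None] = {}
            for r in reads:
                seen.setdefault(r.individual_id, None)
            individuals = list(seen)
        index = {ind: i for i, ind in enumerate(individuals)}
        alleles = np.full((len(reads), m_snps), -1, dtype=np.int8)
        read_ind = np.empty(len(reads), dtype=np.int64)
        ids = []
        for k, r in enumerate(reads):
            if r.individual_id not in index:
                raise ValueError(f"unknown individual {r.individual_id!r}")
            read_ind[k] = index[r.individual_id]
            ids.append(r.read_id)
            for s, a in r.observations:
                if s >= m_snps:
                    raise ValueError(f"site index {s} out of range for m={m_snps}")
                alleles[k, s] = a
        return cls(individuals, m_snps, alleles, read_ind, ids)

    # -- views ---------------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.individuals)

    @property
    def n_reads(self) -> int:
        return self.alleles.shape[0]

    def reads_for(self, individual: int | str) -> list[Read]:
        """Materialize Read objects for one individual."""
        if isinstance(individual, str):
            individual = self.individuals.index(individual)
        out = []
        for k in np.flatnonzero(self.read_individual == individual):
            sites = np.flatnonzero(self.alleles[k] >= 0)
            obs = tuple((int(s), int(self.alleles[k, s])) for s in sites)
            rid = self.read_ids[k] if self.read_ids is not None else f"r{k}"
            out.append(Read(self.individuals[individual], rid, obs))
        return out

    def to_reads(self) -> list[Read]:
        out = []
        for k in range(self.n_reads):
            sites = np.flatnonzero(self.alleles[k] >= 0)
            obs = tuple((int(s), int(self.alleles[k, s])) for s in sites)
            rid = self.read_ids[k] if self.read_ids is not None else f"r{k}"
            out.append(Read(self.individuals[self.read_individual[k]], rid, obs))
        return out

    def restrict_sites(self, sites: Sequence[int]) -> "ReadSets":
        """Keep only the given window sites (re-indexed 0..len(sites)-1).

        Reads covering none of the sites are kept as all-missing rows; they
        contribute empty products (likelihood 1) everywhere.
        """
        sites = list(sites)
        sub = self.alleles[:, sites]
        return ReadSets(self.individuals, len(sites), sub, self.read_individual, self.read_ids)

    def flip_sites(self, sites: Sequence[int]) -> "ReadSets":
        """Return a copy with the allele coding of the given sites inverted."""
        alleles = self.alleles.copy()
        for j in sites:
            col = alleles[:, j]
            observed = col >= 0
            col[observed] = 1 - col[observed]
        return ReadSets(self.individuals, self.m, alleles, self.read_individual, self.read_ids)


@dataclass
class PhyloTree:
    """Rooted perfect-phylogeny tree over a set of window SNPs.

    ``snps`` lists the window site indices covered by the tree, in the
    column order used by the node haplotypes. Node 0 is the root (the
    all-zero, all-ancestral haplotype); every other node has a parent and
    the SNP labelling its parent edge. Node haplotypes are determined by
    the root path: a node carries allele 1 exactly at the edge labels on
    its path from the root.
    """

    snps: list[int]
    parents: list[int | None]
    edge_snps: list[int | None]
    frequencies: np.ndarray | None = None
    root: int = 0

    def __post_init__(self) -> None:
        if self.parents[self.root] is not None or self.edge_snps[self.root] is not None:
            raise ValueError("root must have no parent edge")
        if self.frequencies is not None:
            self.frequencies = np.asarray(self.frequencies, dtype=float)

    @property
    def n_nodes(self) -> int:
        return len(self.parents)

    @property
    def m(self) -> int:
        return len(self.snps)

    def children(self, v: int) -> list[int]:
        return [u for u, p in enumerate(self.parents) if p == v]

    def haplotypes(self) -> list[tuple[int, ...]]:
        """Node haplotypes in node order, columns ordered as ``self.snps``."""
        col = {snp: k for k, snp in enumerate(self.snps)}
        haps: list[list[int] | None] = [None] * self.n_nodes
        haps[self.root] = [0] * self.m

        # parents may appear in any order; resolve by repeated sweeps
        remaining = set(range(self.n_nodes)) - {self.root}
        while remaining:
            progressed = False
            for v in list(remaining):
                p = self.parents[v]
                assert p is not None
                if haps[p] is not None:
                    h = list(haps[p])
                    h[col[self.edge_snps[v]]] = 1
                    haps[v] = h
                    remaining.discard(v)
                    progressed = True
            if not progressed:
                raise ValueError("tree has unreachable nodes or a cycle")
        return [tuple(h) for h in haps]  # type: ignore[arg-type]

    def haplotype_set(self) -> set[tuple[int, ...]]:
        return set(self.haplotypes())

    def validate(self) -> None:
        """Check the perfect-phylogeny invariants; raise ValueError if broken."""
        labels = [s for s in self.edge_snps if s is not None]
        if sorted(labels) != sorted(self.snps):
            raise ValueError("each SNP must label exactly one edge")
        if self.n_nodes != self.m + 1:
            raise ValueError("tree must have m+1 nodes")
        haps = self.haplotypes()
        if haps[self.root] != tuple([0] * self.m):
            raise ValueError("root haplotype must be all zeros")
        if len(set(haps)) != self.n_nodes:
            raise ValueError("node haplotypes must be distinct")
        if self.frequencies is not None:
            p = self.frequencies
            if p.shape != (self.n_nodes,):
                raise ValueError("frequency vector has wrong shape")
            if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-8:
                raise ValueError("frequencies must be a distribution")

    # -- serialization -------------------------------------------------

    def to_table(self) -> list[dict]:
        haps = self.haplotypes()
        rows = []
        for v in range(self.n_nodes):
            rows.append(
                {
                    "node": v,
                    "parent": self.parents[v] if self.parents[v] is not None else -1,
                    "snp": self.edge_snps[v] if self.edge_snps[v] is not None else -1,
                    "haplotype": "".join(map(str, haps[v])),
                    "p_v": float(self.frequencies[v]) if self.frequencies is not None else float("nan"),
                }
            )
        return rows

    def to_newick(self) -> str:
        haps = self.haplotypes()

        def label(v: int) -> str:
            h = "".join(map(str, haps[v]))
            p = f":{self.frequencies[v]:.6g}" if self.frequencies is not None else ""
            snp = self.edge_snps[v]
            tag = f"snp{snp}_" if snp is not None else "root_"
            return f"{tag}{h}{p}"

        def render(v: int) -> str:
            kids = self.children(v)
            if not kids:
                return label(v)
            return "(" + ",".join(render(u) for u in kids) + ")" + label(v)

        return render(self.root) + ";"


@dataclass(frozen=True)
class SimulationParams:
    """Parameters of the read simulator.

    coverage_k is the expected number of reads overlapping a base;
    error_rate is the per-base probability of reading the wrong allele.
    """

    n_individuals: int
    m_snps: int
    coverage_k: float
    read_length_l: int
    error_rate: float
    region_length: int
    snp_positions: tuple[int, ...] | None = None
    min_hap_freq: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.error_rate < 0.5):
            raise ValueError("error_rate must satisfy 0 <= eps < 0.5")
        if self.coverage_k <= 0:
            raise ValueError("coverage must be positive")
        if self.read_length_l < 1:
            raise ValueError("read length must be >= 1")
        if self.read_length_l > self.region_length:
            raise ValueError("read length exceeds region length")
        if self.m_snps < 1:
            raise ValueError("need at least one SNP")
        if self.min_hap_freq * (self.m_snps + 1) > 1 + 1e-12:
            raise ValueError("min_hap_freq infeasible: min_freq*(m+1) must be <= 1")
        pos = self.snp_positions
        if pos is None:
            spacing = self.region_length / (self.m_snps + 1)
            pos = tuple(int(round(spacing * (j + 1))) for j in range(self.m_snps))
        pos = tuple(int(p) for p in pos)
        if len(pos) != self.m_snps:
            raise ValueError("snp_positions length must equal m_snps")
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError("snp_positions must be strictly increasing")
        if pos[0] < 1 or pos[-1] > self.region_length:
            raise ValueError("snp_positions must lie within [1, region_length]")
        object.__setattr__(self, "snp_positions", pos)
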