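# pphs — perfect-phylogeny haplotype phasing from sequencing reads

`pphs` phases diploid individuals from short-read sequencing data when the
population is small and the coverage is low — the regime where
genotype-based phasers lose accuracy and single-individual assembly
methods (which need long, deep reads) cannot operate at all. It exploits
two properties of sequencing data: every read comes from a single
chromosome, so the variants it covers are a fragment of one haplotype;
and SNP density is high, so neighbouring sites are strongly correlated.

## The model

Within a short window of `m` biallelic SNPs the haplotypes are assumed to
follow a **perfect phylogeny**: a rooted tree `T = (V, E)` whose root is
the all-zero (all-ancestral) haplotype, where each SNP mutates 0 → 1 on
exactly one edge and never recurs. A window of `m` SNPs therefore admits
exactly `m + 1` haplotypes, one per node `v`, each with a population
frequency `p_v`. Reads are modelled with a symmetric per-base error rate
ε: a read `r` covering sites `S` given a haplotype pair `(h¹, h²)` has

    Pr(r | h¹, h²) = ½ ε^d₁ (1−ε)^{|S|−d₁} + ½ ε^d₂ (1−ε)^{|S|−d₂}

with `d_i` the Hamming distance between `r` and `h^i` on `S`.

The tree is reconstructed recursively from reads alone:

1. **Allele frequencies.** Per SNP, an EM algorithm maximizes
   `Σᵢ log Σ_g A_{i,j,g} C(2,g) f_j^g (1−f_j)^{2−g}` where
   `A_{i,j,g} = Π_{r∈R_ij} Pr(r | G_ij = g)` are precomputed genotype
   likelihoods. The SNP with the largest frequency cannot descend from any
   other and is anchored as the edge `j*` adjacent to the root.
2. **Partitioning.** The remaining SNPs are split into the side subtree
   T1 and the subtree below `j*`. *PPHS-2* decides each SNP independently
   by comparing the maximized likelihoods of the two minimal two-SNP
   models; *PPHS-3* fits all three-SNP subtree hypotheses for every SNP
   pair by EM, combines them into four configuration-weight graphs, and
   maximizes the summed consistent weights over partitions (exactly for
   small windows, by random-subset majority vote for large ones).
3. **Haplotype calling.** Each individual gets the pair maximizing
   `Pr(h¹)Pr(h²) Π_r Pr(r | h¹, h²)` over the tree's haplotypes plus all
   their one-mutation derivatives, with sequentially updated Dirichlet
   priors (`p_h ∝ n_h + α_h − 1`).
4. **Stitching.** Window solutions are oriented and concatenated against
   an externally phased scaffold using the `d₁/d₂ ≤ d*` Hamming rule;
   windows too far from the scaffold fall back to it.

A coalescent-style simulator (perfect-phylogeny haplotype pools with a
frequency floor, uniform read starts, per-base errors) and the evaluation
metrics — switch+mismatch (SM) error, tree accuracy `Σ_{i∈S} p_i`, and
the MinSingleErr single-individual lower bound — are part of the package,
so the whole method is testable without external data.

## Worked example

```sh
pphs simulate --n 5 --m 30 --coverage 5 --read-length 400 \
    --error-rate 0.03 --seed 7 --out-prefix demo
# simulated 5 individuals, 751 informative reads, 30 SNPs -> demo.*

pphs phase --fragments demo.frags.tsv --sites demo.truth.vcf \
    --scaffold demo.truth.vcf --window-length 5 --error-rate 0.03 \
    --seed 7 --out phased.vcf
# phased 5 individuals over 6 windows -> phased.vcf

pphs evaluate --truth demo.truth.vcf --inferred phased.vcf --out report.tsv
# SM total 4 (S=2, M=2) over 20 het sites -> report.tsv
```

The evaluation report (TSV) lists per-individual switch errors, mismatch
errors, separately counted hom-called-het sites, and the SM total over
truth-heterozygous sites:

```
individual  window  switches  mismatches  hom_mismatches  sm_total  het_sites
ind0        -1      0         0           1               0         5
ind4        -1      0         1           1               1         4
ALL         -1      2         2           4               4         20
```

Here 5 individuals at coverage 5 with 3% read errors are phased with 2
switch and 2 mismatch errors over 20 heterozygous sites — the kind of
operating point (tiny cohort, noisy low-coverage reads) the method is
built for. With `--error-rate 0` and window-spanning reads the SM total
is exactly 0.

The same operations are available as a library (`pphs.simulate_dataset`,
`pphs.reconstruct_tree`, `pphs.phase_window`, `pphs.run_pipeline`, ...);
see `docs/methods.md` for the full model description and parameter
reference.

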