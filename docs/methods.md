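# Methods

This note documents the statistical model, the algorithms, the tunable
parameters, and the design decisions behind `pphs`, in the order the
pipeline runs them.

## Sequencing model and likelihood

A window holds `m` biallelic SNPs, indexed 0-based; alleles are coded
{0, 1} with 0 the ancestral (and, after optional recoding, major) allele.
Individual `i` carries an unobserved haplotype pair `H_i = (h¹, h²)`.
Each read starts uniformly in the region, copies `l` bases from a
fair-coin chromosome, and flips every covered SNP allele independently
with probability ε (`0 ≤ ε < 0.5`, constant across positions — no
position- or cycle-dependent error profile). Reads covering no SNP carry
no information and are dropped. The read likelihood is the equal mixture

    Pr(r | H_i) = ½ ε^{d(h¹_S, r)} (1−ε)^{|S|−d(h¹_S, r)}
                + ½ ε^{d(h²_S, r)} (1−ε)^{|S|−d(h²_S, r)}

over the covered sites `S`. Each mixture term uses its own haplotype's
Hamming distance; with that convention the expression sums to 1 over all
`2^{|S|}` possible reads (a property test checks this exhaustively).
The cohort likelihood is the product over individuals and reads. All
multi-read accumulation is done in log space: at realistic coverage the
products run over hundreds of reads and underflow in linear space.

Per-site genotype likelihoods `A_{i,j,g} = Π_{r∈R_ij} Pr(r | G_ij = g)`
(`g ∈ {0,1,2}`, `A = 1` for uncovered sites) are precomputed once per
window in linear time; the single-site factors are `1−ε`/`ε` for
homozygous genotypes and ½ for heterozygotes. Re-indexed by the unordered
pair {(0,0), (1,0), (1,1)} these triples are exactly what a scaffold
phaser consumes, and can be exported as log10 GL fields in VCF.

## Allele-frequency EM and root-SNP selection

Per SNP the minor-allele frequency `f_j` maximizes

    log L(f_j) = Σ_i log Σ_g A_{i,j,g} C(2,g) f_j^g (1−f_j)^{2−g}.

The EM treats each individual's genotype as latent: the E-step computes
posterior genotype probabilities under the Hardy–Weinberg prior, the
M-step sets `f` to the posterior mean dosage over `2n` chromosomes.
Initialization is the naive fraction of allele-1 observations among
covering reads (0.5 with no reads, where the likelihood is flat and the
initialization is returned unchanged). Convergence: absolute
log-likelihood change below 1e-6, at most 1000 iterations; a numerical
guard keeps the previous iterate if an update would decrease the
likelihood. Tests verify agreement with a grid-search maximizer (step
1e-3) to 2e-3 and the monotone likelihood trace.

Because the tree is rooted at the all-zero haplotype, SNP `j` cannot
descend from `j'` when `f_j > f_{j'}`; the SNP with the largest estimated
frequency is anchored as the root-adjacent edge `j*`, ties broken toward
the lowest index (a deterministic refinement of an arbitrary tie-break).

In the pipeline (not in the bare tree builder) sites with `f̂ > 0.5` are
recoded so 0 is the major allele; flips are recorded per window and
undone on output. The simulator emits ancestral-coded data, so recoding
only matters for externally supplied fragment files.

## Tree reconstruction

Reconstruction is recursive: anchor `j*`, partition the remaining SNPs
into T1 (beside the root) and T2 (below `j*`), hang T1's subtree at the
current root and T2's below the `j*` edge, recurse. Base cases: the empty
set is a leaf, a singleton is a single edge. The same partitioning
machinery is applied at every recursion depth, and all individuals are
retained when recursing (no conditioning on carrying `j*`); reads are
implicitly restricted because deeper levels only evaluate their own
sites.

**PPHS-2** scores each SNP `j` independently. The reads restricted to
`{j*, j}` are evaluated under the two minimal perfect-phylogeny models —
haplotypes {00, 10, 01} (`j` beside `j*`) versus {00, 10, 11} (`j` below
`j*`) — each with frequencies maximized by the mixture EM below,
initialized from the per-SNP frequencies (`[1−f*−f_j, f*, f_j]` and
`[1−f*, f*−f_j, f_j]`, clamped and renormalized). The SNP joins the side
with the higher maximized likelihood; ties (margin 10× the EM tolerance,
so convergence residue cannot break them) go to T1. This is the noisy
four-gamete test: which of the patterns 01 / 11 the reads support.

**PPHS-3** scores SNP pairs jointly. For every pair `(j1, j2)` and each
side configuration `(a, b) ∈ {1,2}²` it enumerates the consistent
three-SNP subtrees over `{j*, j1, j2}` — three topologies for same-side
configurations (siblings, `j2` under `j1`, `j1` under `j2`), one for the
mixed ones, eight in total — fits each subtree's node frequencies by EM,
and sets the configuration weight to the mean of `Pr(R | T*)` over its
topologies. The partition `(S1, S2)` then maximizes
`Σ_{a,b} Σ_{j1∈Sa, j2∈Sb} w^{ab}_{j1 j2}`: exactly, by enumerating all
`2^K` assignments, for up to 12 non-root SNPs (configurable); above that
by solving random subsets of 10 SNPs exactly (`10·⌈K/10⌉·5` subsets) and
taking per-SNP majority votes, ties to S1. A flat objective returns
all-T1 (the enumeration starts there and requires strict improvement).

*Weight normalization (design choice).* Restricted-data likelihoods for
different site triples differ by many orders of magnitude (they are
products over different read observations), so on any common scale the
summed objective is numerically dominated by whichever pair happens to
have the largest likelihood. Each pair's four weights are therefore
divided by that pair's best topology likelihood, putting every pair's
configuration evidence on a comparable (0, 1] scale while preserving the
pair's own preference ordering. Without this, PPHS-2 and PPHS-3 visibly
disagree even on noiseless, well-separated data.

**Haplotype-frequency mixture EM.** Individuals are mixtures over ordered
node pairs drawn `p_a p_b`; the E-step computes pair posteriors, the
M-step averages expected haplotype counts over `2n` chromosomes.
Likelihoods restricted to ≤ 3 sites are vectorized through observation
pattern counts (base-3 codes over missing/0/1), so the per-iteration cost
is independent of read depth. Initialization uses the parent-minus-
children identity `p_v = f(parent edge) − Σ f(child edges)` (1 for the
root's virtual parent), which is exact when the allele frequencies are
exact; under noise it can go negative, so entries are clamped at 1e-6 and
renormalized, with a uniform fallback if nothing is positive. ε is
floored at 1e-12 inside these internals so noiseless data stays finite in
log space; the exact single-read likelihood API is not floored.

The final tree's node frequencies come from the same parent-minus-
children formula applied to the reconstructed topology — they are
estimates read off the per-SNP EM, not a joint fit over the whole window.

## Haplotype calling

The candidate pool is the list L of tree-node haplotypes plus every
Hamming-1 neighbour of an L member not already in L (deduplicated). This
tolerates one recurrent mutation per haplotype — and, since both slots of
a pair may hold derived haplotypes, up to one per chromosome copy.
Individuals are processed in input order; each receives the unordered
pair maximizing `Pr(h¹) Pr(h²) Π_r Pr(r | h¹, h²)` by exhaustive search,
ties broken lexicographically. Priors are the Dirichlet-posterior mode
`p_h ∝ n_h + α_h − 1` over usage counts `n_h` of already-phased
individuals, with `α1 = 2.0` on L members and `α2 = 1.2` on derived ones
(defaults; both configurable). These defaults keep L members strictly
favoured while leaving unused derived candidates positive mass — the mode
formula requires `α > 1` to stay a distribution, which the code enforces.
Derived haplotypes keep their own counts, separate from their L parents.
An individual with no reads receives the two highest-prior candidates.

## Stitching

Windows tile the region consecutively without overlap (default length
5 SNPs; the last window may be shorter). Per window and individual the
two orientation distances to the scaffold are
`d₁ = d(h¹_w, h¹'_w) + d(h²_w, h²'_w)` and the crossed `d₂`. If
`d₁ < d₂` and `d₁ ≤ d*` the window pair is kept in scaffold orientation;
if `d₂ < d₁` and `d₂ ≤ d*` it is kept swapped; in all other cases —
including ties — the scaffold's haplotypes are copied, on the reasoning
that a window far from the scaffold likely violates the perfect-phylogeny
assumption. `d*` defaults to `⌊m/2⌋` and scales as `⌊len/2⌋` for a short
trailing window.

## Evaluation metrics

**SM error.** Over the truth-heterozygous sites of one individual: a site
whose inferred genotype is not heterozygous is a mismatch (M) and is
excluded; over the remaining het sites in order, the orientation (which
inferred haplotype matches truth haplotype 1) is tracked and each
adjacent flip is a switch (S). The report carries S, M, their total, the
het-site count (so both per-window totals and per-het-site rates can be
formed), and — separately, outside the total — truth-homozygous sites
called heterozygous. This counting reproduces the two canonical cases:
(11,00) phased as (10,01) is one switch; as (11,01), one mismatch.

**Tree accuracy.** `Σ_{i∈S} p_i` with `S` the intersection of the true
and reconstructed haplotype sets and `p` the true frequencies: 1 exactly
when the reconstruction recovers every haplotype.

**MinSingleErr.** Per site, the MAP genotype under a uniform prior from
`A_{i,j,·}`; no-call when no read covers the site (likelihood ties break
toward heterozygous); a called het site counts as correctly phased by
construction. Error and no-call rates are over all window sites. Any
method phasing one individual at a time can do no better, so these rates
lower-bound single-individual assembly approaches.

## Synthetic data

The simulator provides the study conditions end to end. Topology: each of
the `m` SNP edges attaches to a uniformly random existing node, giving
`m + 1` distinct haplotypes. Frequencies: uniform on the sub-simplex
`{p : p_v ≥ min_hap_freq}`, realized as
`min_freq + (1 − (m+1)·min_freq) · Dirichlet(1, …, 1)` — the exact
conditional law of a flat Dirichlet given the floor (the direct
rejection-sampling formulation has acceptance probability ~`0.07³⁰` at
`m = 30`, floor 3%). Diploids draw both haplotypes i.i.d. from `p`. The
read count per individual is the deterministic `round(k·G/l)` rather than
Poisson — only expected coverage semantics are modelled. SNP positions
default to uniform spacing `G/(m+1)`. All randomness flows from one
integer seed.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: recombination and recurrent mutation (the model
assumption itself), indels, paired-end reads, quality-score profiles,
position-dependent error rates, population structure, and genotyping
error in the truth. The defaults mirror the simulated study conditions:
minimum haplotype frequency 3%, 30 SNPs per region for tree-accuracy
experiments, window length 5 and 5 individuals at coverage ~5 with 2–4%
errors for phasing experiments, read length 400.

## Problem sizes and numerical choices

The test suite and the acceptance script run reduced replicate counts of
the study conditions (e.g. 50 seeds for noiseless recovery; 15–20
replicates per population size for the convergence trend, against 100 in
a full study), chosen so the whole suite completes in about a minute
while keeping standard errors small relative to the effects checked.
Numerical constants: EM tolerances 1e-6 (log-likelihood units), frequency
clamp 1e-6, internal ε floor 1e-12, partition tie epsilon 1e-12,
PPHS-2 tie margin 10× the EM tolerance. Degenerate inputs: empty windows
are leaves; an individual with no reads gets prior-only calls; flat
likelihoods return their initialization and flat partition objectives
return all-T1.

## Known limitations

- The perfect-phylogeny assumption bounds usable window lengths; the
  window length is a fixed parameter, not adapted to local LD.
- PPHS-3 costs O(K²) EM fits per recursion level and is intended for
  window-scale K; PPHS-2 is the default.
- The stitcher consumes an existing scaffold; the package does not
  generate one (the GL export exists to feed external phasers).
- Sequential MAP calling depends on individual order; `phase_window`
  takes an explicit processing-order argument for sensitivity checks, but
  no joint population MAP is attempted.
- Node frequencies of the final tree are derived from per-SNP estimates,
  not refit jointly; they are diagnostics, not calibrated posteriors.
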