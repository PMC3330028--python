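"""Minor-allele-frequency estimation by EM and root-SNP selection.

The per-SNP likelihood marginalizes the unknown genotypes under a
Hardy-Weinberg prior:

    log L(f_j) = sum_i log sum_g A[i,j,g] * C(2,g) f_j^g (1-f_j)^(2-g)

The EM treats each individual's genotype as the latent variable: the
E-step computes posterior genotype probabilities, the M-step sets f to the
posterior mean allele dosage over 2n chromosomes. Because the tree is
rooted at the all-zero haplotype, the SNP with the largest frequency of
allele 1 cannot be a descendant of any other SNP, and is taken as the edge
adjacent to the root.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["AlleleFreqEstimate", "em_allele_frequency", "grid_search_frequency", "select_root_snp"]

_HWE_LOG_COEF = np.log(np.array([1.0, 2.0, 1.0]))


@dataclass(frozen=True)
class AlleleFreqEstimate:
    snp_index: int
    frequency: float
    log_likelihood: float
    iterations: int
    converged: bool = True


def _log_likelihood(logA: np.ndarray, f: float) -> float:
    f = min(max(f, 1e-15), 1 - 1e-15)
    logpri = _HWE_LOG_COEF + np.array([0.0, 1.0, 2.0]) * np.log(f) + np.array(
        [2.0, 1.0, 0.0]
    ) * np.log(1 - f)
    per_ind = _logsumexp(logA + logpri, axis=1)
    return float(per_ind.sum())


def _logsumexp(x: np.ndarray, axis: int) -> np.ndarray:
    m = np.max(x, axis=axis, keepdims=True)
    m = np.where(np.isfinite(m), m, 0.0)
    return (m + np.log(np.exp(x - m).sum(axis=axis, keepdims=True))).squeeze(axis)


def em_allele_frequency(
    A_slice: np.ndarray,
    snp_index: int = 0,
    tol: float = 1e-6,
    max_iter: int = 1000,
    init: float | None = None,
    log: bool = False,
) -> AlleleFreqEstimate:
    """Maximize the HWE-mixture likelihood of one SNP's genotype triples.

    ``A_slice`` is (n, 3); pass ``log=True`` when the triples are already
    log-scaled (products over many reads underflow on the linear scale).
    Initialization defaults to 0.5 when not given.
    """
    A = np.asarray(A_slice, dtype=float)
    if A.ndim != 2 or A.shape[1] != 3:
        raise ValueError("A_slice must be (n, 3)")
    if log:
        logA = A
        if A.size and not np.all(np.isfinite(A.max(axis=1))):
            raise ValueError("each log triple needs at least one finite entry")
    else:
        if np.any(A <= 0):
            raise ValueError("genotype likelihood triples must be positive")
        logA = np.log(A)
    n = A.shape[0]
    f = 0.5 if init is None else float(min(max(init, 1e-6), 1 - 1e-6))
    if n == 0:
        return AlleleFreqEstimate(snp_index, f, 0.0, 0)

    prev = _log_likelihood(logA, f)
    it = 0
    converged = False
    dosage = np.array([0.0, 1.0, 2.0])
    for it in range(1, max_iter + 1):
        fc = min(max(f, 1e-15), 1 - 1e-15)
        logpri = (
            _HWE_LOG_COEF + dosage * np.log(fc) + (2.0 - dosage) * np.log(1 - fc)
        )
        logpost = logA + logpri
        logpost -= logpost.max(axis=1, keepdims=True)
        post = np.exp(logpost)
        post /= post.sum(axis=1, keepdims=True)
        f_new = float((post @ dosage).sum()) / (2 * n)
        cur = _log_likelihood(logA, f_new)
        if cur < prev - 1e-9:  # EM cannot decrease; numerical guard keeps old f
            break
        f = f_new
        if cur - prev < tol:
            prev = cur
            converged = True
            break
        prev = cur
    return AlleleFreqEstimate(snp_index, f, prev, it, converged or it == 0)


def grid_search_frequency(
    A_slice: np.ndarray, step: float = 1e-3, snp_index: int = 0, log: bool = False
) -> AlleleFreqEstimate:
    """Brute-force maximizer of the same likelihood on a frequency grid."""
    A = np.asarray(A_slice, dtype=float)
    logA = A if log else np.log(A)
    grid = np.arange(0.0, 1.0 + step / 2, step)
    vals = np.array([_log_likelihood(logA, f) for f in grid])
    k = int(np.argmax(vals))
    return AlleleFreqEstimate(snp_index, float(grid[k]), float(vals[k]), 0)


def naive_frequency_init(alleles_at_site: np.ndarray) -> float:
    """Fraction of allele-1 observations among covering reads; 0.5 if none."""
    obs = alleles_at_site[alleles_at_site >= 0]
    if obs.size == 0:
        return 0.5
    return float(obs.mean())


def select_root_snp(estimates: Sequence[AlleleFreqEstimate]) -> int:
    """SNP with the largest estimated frequency; ties go to the lowest index."""
    if not estimates:
        raise ValueError("no estimates given")
    best = max(estimates, key=lambda e: (e.frequency, -e.snp_index))
    return best.snp_index
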