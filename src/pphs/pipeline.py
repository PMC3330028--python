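"""Pipeline drivers: window tiling, per-window phasing, optional stitching.

The region's SNPs are tiled into consecutive non-overlapping windows of
``window_length`` sites (the last possibly shorter). Per window:
allele-frequency EM, optional recoding so that 0 is the major allele,
tree reconstruction, and sequential MAP haplotype assignment. With a
scaffold, windows are oriented and concatenated by the stitcher.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np

from .caller import phase_window
from .io import RunConfig
from .stitcher import StitchChoice, StitchConfig, stitch_windows
from .tree_builder import estimate_frequencies, reconstruct_tree
from .types import HaplotypePair, PhyloTree, ReadSets

__all__ = ["WindowResult", "PipelineResult", "phase_region", "run_pipeline"]

log = logging.getLogger("pphs")


@dataclass
class WindowResult:
    start: int  # window site span [start, stop) in region site indices
    stop: int
    tree: PhyloTree  # in window-local (possibly recoded) coordinates
    pairs: list[HaplotypePair]  # in original allele coding
    flipped_sites: list[int]  # window-local sites recoded (major allele was 1)
    root_snp: int  # window-local index of the SNP adjacent to the root
    elapsed: float


@dataclass
class PipelineResult:
    windows: list[WindowResult]
    stitched: list[HaplotypePair] | None = None
    decisions: list[list[StitchChoice]] | None = None

    def concatenated(self) -> list[HaplotypePair]:
        """Window pairs concatenated as-is (orientation arbitrary per window)."""
        n = len(self.windows[0].pairs)
        out = []
        for i in range(n):
            h1 = tuple(x for w in self.windows for x in w.pairs[i].h1)
            h2 = tuple(x for w in self.windows for x in w.pairs[i].h2)
            out.append(HaplotypePair(self.windows[0].pairs[i].individual_id, h1, h2))
        return out


def _unflip(pair: HaplotypePair, flipped: list[int]) -> HaplotypePair:
    if not flipped:
        return pair
    h1, h2 = list(pair.h1), list(pair.h2)
    for j in flipped:
        h1[j] = 1 - h1[j]
        h2[j] = 1 - h2[j]
    return HaplotypePair(pair.individual_id, tuple(h1), tuple(h2))


def phase_region(
    reads: ReadSets, config: RunConfig, rng: np.random.Generator | None = None
) -> list[WindowResult]:
    """Phase every window of the region independently."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    eps = config.error_rate
    results = []
    for start in range(0, reads.m, config.window_length):
        t0 = time.perf_counter()
        stop = min(start + config.window_length, reads.m)
        sub = reads.restrict_sites(range(start, stop))
        mloc = stop - start
        estimates = estimate_frequencies(sub, range(mloc), eps)

        flipped: list[int] = []
        if config.recode_major_allele:
            flipped = [j for j in range(mloc) if estimates[j].frequency > 0.5]
            if flipped:
                sub = sub.flip_sites(flipped)
                upd = estimate_frequencies(sub, flipped, eps)
                estimates = {**estimates, **upd}

        tree = reconstruct_tree(
            sub,
            list(range(mloc)),
            eps,
            method=config.partition_method,
            rng=rng,
            max_enumeration=config.max_enumeration_m,
            estimates=estimates,
        )
        pairs = phase_window(sub, tree, config.alpha1, config.alpha2, eps)
        pairs = [_unflip(p, flipped) for p in pairs]
        root_children = tree.children(tree.root)
        root_snp = min(tree.edge_snps[c] for c in root_children) if root_children else -1
        elapsed = time.perf_counter() - t0
        log.info(
            "window %d-%d: j*=%d, |T|=%d nodes, flips=%s, %.2fs",
            start,
            stop,
            root_snp,
            tree.n_nodes,
            flipped,
            elapsed,
        )
        results.append(WindowResult(start, stop, tree, pairs, flipped, root_snp, elapsed))
    return results


def run_pipeline(
    reads: ReadSets,
    config: RunConfig,
    scaffold: list[HaplotypePair] | None = None,
    rng: np.random.Generator | None = None,
) -> PipelineResult:
    """Phase all windows and, when a scaffold is given, stitch them."""
    windows = phase_region(reads, config, rng)
    result = PipelineResult(windows)
    if scaffold is not None:
        spans = [(w.start, w.stop) for w in windows]
        cfg = StitchConfig(config.window_length, config.d_star)
        stitched, decisions = stitch_windows(
            [w.pairs for w in windows], scaffold, cfg, spans
        )
        result.stitched = stitched
        result.decisions = decisions
        n_win = len(windows) * len(scaffold)
        kept = sum(1 for row in decisions for c in row if c is not StitchChoice.SCAFFOLD)
        log.info("stitching: window solution kept in %d/%d cases", kept, n_win)
    return result
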