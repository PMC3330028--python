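"""Stitching window haplotypes into full haplotypes against a scaffold.

Within-window phasing leaves the relative orientation of consecutive
windows undetermined. An externally phased scaffold (e.g. a population
phaser's output) fixes it: per window and individual, the two Hamming
distances between the window pair and the scaffold pair (identity and
swapped orientation) are compared. If the closer orientation is within a
threshold d* the window haplotypes are kept in that orientation; otherwise
the perfect-phylogeny model is assumed broken in this window and the
scaffold haplotypes are copied verbatim.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

from .types import HaplotypePair

__all__ = ["StitchConfig", "StitchChoice", "window_distances", "stitch_decision", "stitch_windows"]


class StitchChoice(Enum):
    WINDOW_ALIGNED = "window_aligned"
    WINDOW_SWAPPED = "window_swapped"
    SCAFFOLD = "scaffold"


@dataclass(frozen=True)
class StitchConfig:
    """d* threshold; defaults to floor(m/2) for a window of length m."""

    window_length: int
    d_star: int | None = None

    def threshold(self, window_len: int | None = None) -> int:
        m = self.window_length if window_len is None else window_len
        if self.d_star is not None:
            # a configured d* scales down with a short trailing window
            if window_len is not None and window_len < self.window_length:
                return min(self.d_star, window_len // 2)
            return self.d_star
        return m // 2


def _hamming(a: Sequence[int], b: Sequence[int]) -> int:
    return sum(x != y for x, y in zip(a, b))


def window_distances(
    window_pair: HaplotypePair, scaffold_pair: HaplotypePair
) -> tuple[int, int]:
    """d1 = identity-orientation distance sum, d2 = swapped orientation."""
    if len(window_pair) != len(scaffold_pair):
        raise ValueError("window and scaffold pairs must have equal length")
    d1 = _hamming(window_pair.h1, scaffold_pair.h1) + _hamming(window_pair.h2, scaffold_pair.h2)
    d2 = _hamming(window_pair.h2, scaffold_pair.h1) + _hamming(window_pair.h1, scaffold_pair.h2)
    return d1, d2


def stitch_decision(d1: int, d2: int, d_star: int) -> StitchChoice:
    """Keep the window pair only when one orientation is strictly closer and
    within d*; everything else (including ties) falls back to the scaffold."""
    if d1 < d2 and d1 <= d_star:
        return StitchChoice.WINDOW_ALIGNED
    if d2 < d1 and d2 <= d_star:
        return StitchChoice.WINDOW_SWAPPED
    return StitchChoice.SCAFFOLD


def stitch_windows(
    window_results: Sequence[Sequence[HaplotypePair]],
    scaffold: Sequence[HaplotypePair],
    config: StitchConfig,
    window_spans: Sequence[tuple[int, int]] | None = None,
) -> tuple[list[HaplotypePair], list[list[StitchChoice]]]:
    """Concatenate per-window pairs into full haplotypes, scaffold-oriented.

    ``window_results[w][i]`` is individual i's pair in window w; windows must
    tile the scaffold length in order. Returns the stitched pairs plus the
    per-window decisions (windows x individuals).
    """
    n = len(scaffold)
    if any(len(wr) != n for wr in window_results):
        raise ValueError("each window must cover every individual")
    if window_spans is None:
        spans = []
        start = 0
        for wr in window_results:
            mlen = len(wr[0]) if wr else 0
            spans.append((start, start + mlen))
            start += mlen
        window_spans = spans
    total = sum(b - a for a, b in window_spans)
    if any(len(scaffold[i]) != total for i in range(n)):
        raise ValueError("windows do not tile the scaffold length")

    decisions: list[list[StitchChoice]] = []
    parts: list[list[HaplotypePair]] = [[] for _ in range(n)]
    for w, (a, b) in enumerate(window_spans):
        row = []
        for i in range(n):
            wp = window_results[w][i]
            if len(wp) != b - a:
                raise ValueError("window pair length does not match its span")
            sp = scaffold[i].slice(a, b)
            d1, d2 = window_distances(wp, sp)
            choice = stitch_decision(d1, d2, config.threshold(b - a))
            row.append(choice)
            if choice is StitchChoice.WINDOW_ALIGNED:
                parts[i].append(wp)
            elif choice is StitchChoice.WINDOW_SWAPPED:
                parts[i].append(wp.swapped())
            else:
                parts[i].append(sp)
        decisions.append(row)

    stitched = []
    for i in range(n):
        h1 = tuple(x for p in parts[i] for x in p.h1)
        h2 = tuple(x for p in parts[i] for x in p.h2)
        stitched.append(HaplotypePair(scaffold[i].individual_id, h1, h2))
    return stitched, decisions
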