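"""Local-background peak significance.

Candidate peaks are local maxima of read-start density in fixed-width tiles;
each is scored against a Poisson rate estimated from a window centered on the
candidate (the candidate tile itself excluded), floored at the chromosome-wide
rate, and the candidate set is FDR-filtered with Benjamini-Hochberg.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .count_model import bh_adjust
from .genome_intervals import GenomicInterval, ReadTrack

__all__ = ["Peak", "call_peaks", "poisson_tail"]


@dataclass(frozen=True)
class Peak:
    interval: GenomicInterval
    read_count: int
    local_lambda: float
    p: float
    padj: float

    def __post_init__(self) -> None:
        if self.read_count < 0:
            raise ValueError("read_count must be >= 0")
        if self.local_lambda <= 0:
            raise ValueError("local_lambda must be > 0")


def poisson_tail(k: int, lam: float) -> float:
    """P(X >= k) for X ~ Poisson(lam)."""
    if k <= 0:
        return 1.0
    return float(stats.poisson.sf(k - 1, lam))


def _tile_counts(starts: np.ndarray, width: int) -> np.ndarray:
    n_tiles = int(starts.max()) // width + 1
    return np.bincount(starts // width, minlength=n_tiles)


def call_peaks(
    track: ReadTrack,
    peak_width: int = 200,
    bg_window: int = 10_000,
    fdr: float = 0.001,
) -> list[Peak]:
    """Call significant peaks against the local 10-kb background.

    Returns peaks with BH-adjusted Poisson upper-tail probability < ``fdr``;
    retained tiles that touch are merged, keeping the best p.
    """
    if bg_window <= peak_width:
        raise ValueError("bg_window must exceed peak_width")
    by_chrom: dict[str, list[int]] = {}
    for r in track.reads:
        by_chrom.setdefault(r.chrom, []).append(r.start)
    if not by_chrom:
        return []

    candidates: list[tuple[str, int, int, float]] = []  # chrom, tile, count, lambda
    half_bg = bg_window // 2
    for chrom, start_list in sorted(by_chrom.items()):
        starts = np.asarray(start_list, dtype=np.int64)
        counts = _tile_counts(starts, peak_width)
        extent = counts.size * peak_width
        global_rate = starts.size * peak_width / extent  # reads per tile
        sorted_starts = np.sort(starts)
        padded = np.concatenate([[0], counts, [0]])
        is_max = (counts > 0) & (counts >= padded[:-2]) & (counts >= padded[2:])
        for tile in np.nonzero(is_max)[0]:
            center = tile * peak_width + peak_width // 2
            lo, hi = center - half_bg, center + half_bg
            n_bg = int(
                np.searchsorted(sorted_starts, hi, side="left")
                - np.searchsorted(sorted_starts, lo, side="left")
            )
            n_obs = int(counts[tile])
            lam = (n_bg - n_obs) * peak_width / (bg_window - peak_width)
            lam = max(lam, global_rate, 1e-9)
            candidates.append((chrom, int(tile), n_obs, lam))

    if not candidates:
        return []
    pvals = np.array([poisson_tail(c[2], c[3]) for c in candidates])
    padj = bh_adjust(pvals)

    kept = [
        (chrom, tile, n_obs, lam, p, q)
        for (chrom, tile, n_obs, lam), p, q in zip(candidates, pvals, padj)
        if q < fdr
    ]
    kept.sort(key=lambda x: (x[0], x[1]))

    merged: list[Peak] = []
    for chrom, tile, n_obs, lam, p, q in kept:
        start, end = tile * peak_width, (tile + 1) * peak_width
        if merged and merged[-1].interval.chrom == chrom and merged[-1].interval.end >= start:
            prev = merged[-1]
            best = prev if prev.p <= p else Peak(
                GenomicInterval(chrom, prev.interval.start, end),
                n_obs, lam, p, q,
            )
            merged[-1] = Peak(
                GenomicInterval(chrom, prev.interval.start, end),
                best.read_count,
                best.local_lambda,
                best.p,
                best.padj,
            )
        else:
            merged.append(Peak(GenomicInterval(chrom, start, end), n_obs, lam, p, q))
    return merged
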