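"""Enhancer-signature statistics: acetylation/methylation promoter ratio,
the enhancer-mark stringency correlation ladder, peak-to-TSS distance
distributions and neighbor-expression response comparisons."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome_intervals import (
    GenomicInterval,
    NeighborPair,
    ReadTrack,
    TranscriptModel,
    count_in_window,
    tss_window,
)

__all__ = [
    "RatioRecord",
    "CorrelationLadder",
    "acetylation_ratio",
    "stringency_correlation",
    "peak_tss_distance",
    "neighbor_response_compare",
]


@dataclass(frozen=True)
class RatioRecord:
    gene_id: str
    log2_ratio: float


@dataclass(frozen=True)
class CorrelationLadder:
    threshold: float
    rho: float | None
    p: float | None
    n: int


def acetylation_ratio(
    lincs_by_group: Mapping[str, Sequence[TranscriptModel]],
    k27ac: ReadTrack,
    k27me3: ReadTrack,
    flank: int = 500,
    pseudocount: float = 1.0,
) -> tuple[dict[str, list[RatioRecord]], float, float]:
    """log2((H3K27ac rpm + pc) / (H3K27me3 rpm + pc)) per lincRNA TSS window,
    plus a one-sided two-sample KS test that the 'ARA' group's ratios are
    stochastically greater than the 'NonA' group's."""
    records: dict[str, list[RatioRecord]] = {}
    for group, models in lincs_by_group.items():
        recs = []
        for t in models:
            w = tss_window(t, flank)
            ac = count_in_window(k27ac, w)
            me = count_in_window(k27me3, w)
            recs.append(RatioRecord(t.gene_id, float(np.log2((ac + pseudocount) / (me + pseudocount)))))
        records[group] = recs
    ara = [r.log2_ratio for r in records.get("ARA", [])]
    nona = [r.log2_ratio for r in records.get("NonA", [])]
    if ara and nona:
        # alternative="less": the ARA empirical CDF lies below NonA's,
        # i.e. ARA ratios are shifted toward larger values
        res = stats.ks_2samp(ara, nona, alternative="less")
        ks_stat, ks_p = float(res.statistic), float(res.pvalue)
    else:
        ks_stat, ks_p = float("nan"), float("nan")
    return records, ks_stat, ks_p


def stringency_correlation(
    pairs: Sequence[NeighborPair],
    groups: Mapping[str, str],
    linc_fc: Mapping[str, float],
    nbr_fc: Mapping[str, float],
    k4me1: ReadTrack,
    k27ac: ReadTrack,
    models: Mapping[str, TranscriptModel],
    thresholds: Sequence[float] = (0.5, 1.0, 1.5, 2.0),
    flank: int = 500,
    method: str = "spearman",
    min_pairs: int = 5,
) -> dict[str, list[CorrelationLadder]]:
    """Correlation between lincRNA and neighbor androgen fold changes at
    increasingly stringent enhancer-mark cutoffs.

    At each threshold t only pairs whose lincRNA TSS window exceeds t rpm in
    BOTH H3K4me1 and H3K27ac are retained. Rungs with fewer than ``min_pairs``
    pairs report rho = None.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError("method must be 'spearman' or 'pearson'")
    per_group: dict[str, list[tuple[float, float, float]]] = {}
    for p in pairs:
        g = groups.get(p.lincrna_id)
        if g is None or p.lincrna_id not in linc_fc or p.pc_id not in nbr_fc:
            continue
        w = tss_window(models[p.lincrna_id], flank)
        level = min(count_in_window(k4me1, w), count_in_window(k27ac, w))
        per_group.setdefault(g, []).append(
            (level, linc_fc[p.lincrna_id], nbr_fc[p.pc_id])
        )
    out: dict[str, list[CorrelationLadder]] = {}
    for g, rows in per_group.items():
        ladder = []
        for t in thresholds:
            kept = [(a, b) for level, a, b in rows if level > t]
            if len(kept) < min_pairs:
                ladder.append(CorrelationLadder(t, None, None, len(kept)))
                continue
            x, y = zip(*kept)
            if method == "spearman":
                res = stats.spearmanr(x, y)
            else:
                res = stats.pearsonr(x, y)
            ladder.append(
                CorrelationLadder(t, float(res.statistic), float(res.pvalue), len(kept))
            )
        out[g] = ladder
    return out


def peak_tss_distance(
    peaks_by_mark: Mapping[str, Sequence[GenomicInterval]],
    tss_by_group: Mapping[str, Sequence[tuple[str, int]]],
) -> tuple[dict[str, dict[str, np.ndarray]], dict[str, float | None]]:
    """Per mark, log2(1 + distance) from each peak midpoint to the nearest TSS
    of each group, and a Welch t-test between the two groups' distributions.

    Peaks on chromosomes where a group has no TSS are skipped for that group.
    """
    group_pos: dict[str, dict[str, np.ndarray]] = {}
    for g, tsss in tss_by_group.items():
        per_chrom: dict[str, list[int]] = {}
        for chrom, pos in tsss:
            per_chrom.setdefault(chrom, []).append(pos)
        group_pos[g] = {c: np.sort(np.asarray(v)) for c, v in per_chrom.items()}

    dists: dict[str, dict[str, np.ndarray]] = {}
    pvals: dict[str, float | None] = {}
    groups = list(tss_by_group)
    for mark, peaks in peaks_by_mark.items():
        dists[mark] = {}
        for g in groups:
            vals = []
            for pk in peaks:
                pos = group_pos[g].get(pk.chrom)
                if pos is None or pos.size == 0:
                    continue
                # any TSS inside the peak means distance zero
                lo = int(np.searchsorted(pos, pk.start, side="left"))
                hi = int(np.searchsorted(pos, pk.end - 1, side="right"))
                if hi > lo:
                    d = 0
                else:
                    mid = (pk.start + pk.end) // 2
                    i = int(np.searchsorted(pos, mid))
                    d = min(
                        abs(mid - int(pos[j])) for j in (i - 1, i) if 0 <= j < pos.size
                    )
                vals.append(np.log2(d + 1))
            dists[mark][g] = np.asarray(vals)
        if len(groups) == 2:
            a, b = dists[mark][groups[0]], dists[mark][groups[1]]
            if a.size >= 2 and b.size >= 2:
                res = stats.ttest_ind(a, b, equal_var=False)
                pvals[mark] = float(res.pvalue)
            else:
                pvals[mark] = None
    return dists, pvals


def neighbor_response_compare(
    pairs: Sequence[NeighborPair],
    groups: Mapping[str, str],
    nbr_fc: Mapping[str, float],
    polII: ReadTrack,
    models: Mapping[str, TranscriptModel],
    up_pc: set[str],
    down_pc: set[str],
    polII_peaks: Sequence[GenomicInterval] | None = None,
    flank: int = 500,
) -> dict[str, dict]:
    """Compare neighbor androgen fold changes between ARA and NonA lincRNAs,
    separately for androgen-activated and androgen-inhibited neighbors.

    Only lincRNAs with a PolII mark at their TSS participate: a significant
    PolII peak overlapping the TSS window when ``polII_peaks`` is given,
    otherwise any PolII read (rpm > 0) in the window.
    """
    def has_polII(linc_id: str) -> bool:
        w = tss_window(models[linc_id], flank)
        if polII_peaks is not None:
            return any(pk.overlaps(w) for pk in polII_peaks)
        return count_in_window(polII, w) > 0

    subsets = {"activated": up_pc, "inhibited": down_pc}
    out: dict[str, dict] = {}
    for name, pc_set in subsets.items():
        ara_vals, nona_vals = [], []
        for p in pairs:
            g = groups.get(p.lincrna_id)
            if g is None or p.pc_id not in pc_set or p.pc_id not in nbr_fc:
                continue
            if not has_polII(p.lincrna_id):
                continue
            (ara_vals if g == "ARA" else nona_vals).append(nbr_fc[p.pc_id])
        if len(ara_vals) < 2 or len(nona_vals) < 2:
            out[name] = {
                "n_ara": len(ara_vals),
                "n_nona": len(nona_vals),
                "p": None,
                "notice": "subset too small for a test",
            }
            continue
        res = stats.ttest_ind(ara_vals, nona_vals, equal_var=False)
        out[name] = {
            "n_ara": len(ara_vals),
            "n_nona": len(nona_vals),
            "ara_mean": float(np.mean(ara_vals)),
            "nona_mean": float(np.mean(nona_vals)),
            "p": float(res.pvalue),
        }
    return out
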