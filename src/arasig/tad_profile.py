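"""TAD assignment, per-TAD peak counts, boundary-distance metric and
TAD-level group comparisons."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome_intervals import GenomicInterval, TranscriptModel

__all__ = [
    "Tad",
    "assign_to_tads",
    "tad_group_flags",
    "tad_peak_counts",
    "boundary_distance",
    "tad_expression_compare",
]


@dataclass(frozen=True)
class Tad:
    interval: GenomicInterval
    id: str


def _check_non_overlapping(tads: Sequence[Tad]) -> None:
    by_chrom: dict[str, list[Tad]] = {}
    for t in tads:
        by_chrom.setdefault(t.interval.chrom, []).append(t)
    for chrom, ts in by_chrom.items():
        ts = sorted(ts, key=lambda t: t.interval.start)
        for a, b in zip(ts, ts[1:]):
            if a.interval.end > b.interval.start:
                raise ValueError(f"overlapping TADs on {chrom}: {a.id} and {b.id}")


def assign_to_tads(
    models: Sequence[TranscriptModel], tads: Sequence[Tad]
) -> dict[str, str]:
    """Map gene_id -> TAD id by TSS containment; genes whose TSS falls in a
    boundary gap are absent from the map. Uses the 5'-most TSS per gene."""
    _check_non_overlapping(tads)
    by_chrom: dict[str, list[Tad]] = {}
    for t in tads:
        by_chrom.setdefault(t.interval.chrom, []).append(t)
    for chrom in by_chrom:
        by_chrom[chrom].sort(key=lambda t: t.interval.start)

    gene_tss: dict[str, tuple[str, int]] = {}
    for m in models:
        cur = gene_tss.get(m.gene_id)
        if cur is None:
            gene_tss[m.gene_id] = (m.chrom, m.tss)
        else:
            better = m.tss < cur[1] if m.strand == "+" else m.tss > cur[1]
            if better:
                gene_tss[m.gene_id] = (m.chrom, m.tss)

    out: dict[str, str] = {}
    for gid, (chrom, tss) in gene_tss.items():
        ts = by_chrom.get(chrom)
        if not ts:
            continue
        starts = [t.interval.start for t in ts]
        i = int(np.searchsorted(starts, tss, side="right")) - 1
        if i >= 0 and ts[i].interval.contains(tss):
            out[gid] = ts[i].id
    return out


def tad_group_flags(
    assignment: Mapping[str, str],
    ara_ids: set[str],
    nona_ids: set[str],
) -> pd.DataFrame:
    """Per-TAD contains_ara / contains_nona flags. A TAD holding both kinds of
    loci appears in both groups."""
    tad_ids = sorted(set(assignment.values()))
    ara_tads = {assignment[g] for g in ara_ids if g in assignment}
    nona_tads = {assignment[g] for g in nona_ids if g in assignment}
    return pd.DataFrame(
        {
            "contains_ara": [t in ara_tads for t in tad_ids],
            "contains_nona": [t in nona_tads for t in tad_ids],
        },
        index=pd.Index(tad_ids, name="tad_id"),
    )


def tad_peak_counts(
    tads: Sequence[Tad],
    peaks_by_mark: Mapping[str, Sequence[GenomicInterval]],
    ara_tad_ids: set[str],
    nona_tad_ids: set[str],
) -> tuple[pd.DataFrame, dict[str, float | None]]:
    """Count FDR-filtered peaks inside each TAD and compare groups per mark.

    A peak straddling a TAD boundary counts in every TAD it overlaps. The
    per-mark test is a one-sided Welch t-test with alternative
    "ARA-containing TADs have more peaks"; marks with fewer than two TADs in
    either group get p = None.
    """
    _check_non_overlapping(tads)
    counts = pd.DataFrame(
        0, index=pd.Index([t.id for t in tads], name="tad_id"),
        columns=list(peaks_by_mark),
    )
    by_chrom: dict[str, list[Tad]] = {}
    for t in tads:
        by_chrom.setdefault(t.interval.chrom, []).append(t)
    for chrom in by_chrom:
        by_chrom[chrom].sort(key=lambda t: t.interval.start)

    for mark, peaks in peaks_by_mark.items():
        for pk in peaks:
            ts = by_chrom.get(pk.chrom)
            if not ts:
                continue
            for t in ts:
                if t.interval.overlaps(pk):
                    counts.at[t.id, mark] += 1

    pvals: dict[str, float | None] = {}
    ara_rows = [t.id for t in tads if t.id in ara_tad_ids]
    nona_rows = [t.id for t in tads if t.id in nona_tad_ids]
    for mark in peaks_by_mark:
        a = counts.loc[ara_rows, mark].to_numpy(dtype=float)
        b = counts.loc[nona_rows, mark].to_numpy(dtype=float)
        if a.size < 2 or b.size < 2:
            pvals[mark] = None
            continue
        res = stats.ttest_ind(a, b, equal_var=False, alternative="greater")
        pvals[mark] = float(res.pvalue) if np.isfinite(res.pvalue) else None
    return counts, pvals


def boundary_distance(tss: int, tad: Tad) -> float:
    """Normalized distance from a TSS to its TAD's nearest boundary: 0% at a
    boundary, 100% at the exact middle of the TAD."""
    iv = tad.interval
    if not iv.contains(tss):
        raise ValueError(f"TSS {tss} outside TAD {tad.id} [{iv.start}, {iv.end})")
    half = len(iv) / 2.0
    return 100.0 * min(tss - iv.start, iv.end - tss) / half


def tad_expression_compare(
    ara_tad_ids: set[str],
    nona_tad_ids: set[str],
    pc_assignment: Mapping[str, str],
    fpkm: Mapping[str, float],
    pseudocount: float = 0.01,
) -> dict[str, float]:
    """Pool log2 FPKM of protein-coding genes inside ARA- vs NonA-containing
    TADs; one-sided Welch t-test with alternative "ARA greater". A gene whose
    TAD is in both groups contributes to both pools."""
    ara_vals, nona_vals = [], []
    for gid, tad_id in pc_assignment.items():
        if gid not in fpkm:
            continue
        v = float(np.log2(fpkm[gid] + pseudocount))
        if tad_id in ara_tad_ids:
            ara_vals.append(v)
        if tad_id in nona_tad_ids:
            nona_vals.append(v)
    if len(ara_vals) < 2 or len(nona_vals) < 2:
        raise ValueError("each TAD group needs >= 2 protein-coding genes")
    res = stats.ttest_ind(ara_vals, nona_vals, equal_var=False, alternative="greater")
    return {
        "ara_mean": float(np.mean(ara_vals)),
        "nona_mean": float(np.mean(nona_vals)),
        "n_ara": len(ara_vals),
        "n_nona": len(nona_vals),
        "p": float(res.pvalue),
    }
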