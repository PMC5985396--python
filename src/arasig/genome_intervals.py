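"""Annotation and interval machinery.

Internal coordinates are 0-based half-open throughout (BED convention);
GTF I/O converts from/to the 1-based closed GTF convention.
"""

from __future__ import annotations

import re
from bisect import insort
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "TranscriptModel",
    "ReadTrack",
    "NeighborPair",
    "read_gtf",
    "write_gtf",
    "read_bed",
    "write_bed",
    "tss_window",
    "count_in_window",
    "count_per_gene",
    "closest_tss",
    "classify_novel_lincrnas",
    "coding_filter",
    "longest_orf",
]

STRANDS = {"+", "-", "."}


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open interval [start, end) on a chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"unknown strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass
class TranscriptModel:
    """A transcript with exon structure, biotype and per-condition FPKM.

    ``exons`` must be sorted, non-overlapping and share chrom/strand.
    The TSS is strand-aware: leftmost coordinate on '+', rightmost on '-'.
    """

    id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[GenomicInterval]
    biotype: str = "lincRNA"
    fpkm: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"transcript {self.id}: strand must be + or -")
        if not self.exons:
            raise ValueError(f"transcript {self.id}: no exons")
        for ex in self.exons:
            if ex.chrom != self.chrom:
                raise ValueError(f"transcript {self.id}: exon on wrong chromosome")
            if ex.strand not in (".", self.strand):
                raise ValueError(f"transcript {self.id}: exon strand mismatch")
        starts = [e.start for e in self.exons]
        if starts != sorted(starts):
            raise ValueError(f"transcript {self.id}: exons not sorted")
        for a, b in zip(self.exons, self.exons[1:]):
            if a.end > b.start:
                raise ValueError(f"transcript {self.id}: overlapping exons")

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)

    def max_fpkm(self) -> float:
        return max(self.fpkm.values()) if self.fpkm else 0.0


class ReadTrack:
    """One epigenetic dataset: aligned-read intervals plus the mapped-read total
    used as normalization denominator."""

    def __init__(self, mark: str, reads: Sequence[GenomicInterval], total_mapped: int):
        reads = list(reads)
        if not reads:
            raise ValueError(f"track {mark}: no reads")
        if total_mapped < len(reads):
            raise ValueError(
                f"track {mark}: total_mapped ({total_mapped}) < number of reads"
            )
        self.mark = mark
        self.reads = reads
        self.total_mapped = int(total_mapped)
        self._index: dict[str, tuple[np.ndarray, np.ndarray]] | None = None

    def _build_index(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        # per chromosome: sorted start positions, and independently sorted ends;
        # overlap count for [s,e) = #{start < e} - #{end <= s}
        if self._index is None:
            by_chrom: dict[str, list[tuple[int, int]]] = {}
            for r in self.reads:
                by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
            idx = {}
            for chrom, pairs in by_chrom.items():
                arr = np.asarray(pairs, dtype=np.int64)
                idx[chrom] = (np.sort(arr[:, 0]), np.sort(arr[:, 1]))
            self._index = idx
        return self._index

    def count_overlaps(self, window: GenomicInterval) -> int:
        idx = self._build_index()
        if window.chrom not in idx:
            return 0
        starts, ends = idx[window.chrom]
        n_before_end = int(np.searchsorted(starts, window.end, side="left"))
        n_ended = int(np.searchsorted(ends, window.start, side="right"))
        return n_before_end - n_ended

    def __repr__(self) -> str:
        return f"ReadTrack({self.mark!r}, n={len(self.reads)}, total={self.total_mapped})"


@dataclass(frozen=True)
class NeighborPair:
    """A lincRNA paired with its closest expressed protein-coding neighbor."""

    lincrna_id: str
    pc_id: str
    tss_distance: int
    orientation: str  # upstream | downstream, relative to lincRNA transcription

    def __post_init__(self) -> None:
        if self.tss_distance < 0:
            raise ValueError("tss_distance must be non-negative")
        if self.orientation not in ("upstream", "downstream"):
            raise ValueError(f"bad orientation {self.orientation!r}")


# ---------------------------------------------------------------------------
# GTF I/O (GENCODE dialect: gene_id/transcript_id attributes, exon features)
# ---------------------------------------------------------------------------

_ATTR_RE = re.compile(r'(\w+) "([^"]*)";?')


def _parse_attrs(s: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(s))


def read_gtf(path: str | Path) -> list[TranscriptModel]:
    """Parse a GENCODE-dialect GTF into transcript models.

    Only ``exon`` features are used; 1-based closed coordinates become
    0-based half-open. Raises ``ValueError`` with the offending line number
    on malformed input.
    """
    per_tx: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 tab-separated fields")
            chrom, _src, feature, start, end, _score, strand, _frame, attrs = fields
            if feature != "exon":
                continue
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: unknown strand {strand!r}")
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start_i < 1 or end_i < start_i:
                raise ValueError(f"{path}:{lineno}: bad coordinate range")
            a = _parse_attrs(attrs)
            if "transcript_id" not in a or "gene_id" not in a:
                raise ValueError(f"{path}:{lineno}: missing gene_id/transcript_id")
            tid = a["transcript_id"]
            rec = per_tx.get(tid)
            if rec is None:
                rec = {
                    "gene_id": a["gene_id"],
                    "chrom": chrom,
                    "strand": strand,
                    "exons": [],
                    "biotype": a.get("gene_biotype", a.get("gene_type", "lincRNA")),
                    "fpkm": {},
                }
                per_tx[tid] = rec
                order.append(tid)
            if chrom != rec["chrom"]:
                raise ValueError(f"{path}:{lineno}: transcript {tid} spans chromosomes")
            if strand != rec["strand"]:
                raise ValueError(f"{path}:{lineno}: transcript {tid} has mixed strands")
            for key, val in a.items():
                m = re.fullmatch(r"fpkm_(\w+)", key)
                if m:
                    rec["fpkm"][m.group(1)] = float(val)
            insort(rec["exons"], GenomicInterval(chrom, start_i - 1, end_i, strand))
    return [
        TranscriptModel(
            id=tid,
            gene_id=rec["gene_id"],
            chrom=rec["chrom"],
            strand=rec["strand"],
            exons=rec["exons"],
            biotype=rec["biotype"],
            fpkm=rec["fpkm"],
        )
        for tid, rec in ((t, per_tx[t]) for t in order)
    ]


def write_gtf(models: Iterable[TranscriptModel], path: str | Path) -> None:
    """Write transcript models as exon lines in GENCODE-dialect GTF."""
    with open(path, "w") as fh:
        for t in models:
            for ex in t.exons:
                attrs = (
                    f'gene_id "{t.gene_id}"; transcript_id "{t.id}"; '
                    f'gene_biotype "{t.biotype}";'
                )
                for cond in sorted(t.fpkm):
                    attrs += f' fpkm_{cond} "{t.fpkm[cond]:.6g}";'
                fh.write(
                    f"{t.chrom}\tarasig\texon\t{ex.start + 1}\t{ex.end}\t.\t"
                    f"{t.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# BED I/O
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED6 into intervals (0-based half-open, as-is)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >= 3 columns")
            strand = f[5] if len(f) >= 6 and f[5] in STRANDS else "."
            out.append(GenomicInterval(f[0], int(f[1]), int(f[2]), strand))
    return out


def write_bed(
    intervals: Iterable[GenomicInterval],
    path: str | Path,
    names: Iterable[str] | None = None,
    scores: Iterable[float] | None = None,
) -> None:
    intervals = list(intervals)
    names = list(names) if names is not None else ["."] * len(intervals)
    scores = list(scores) if scores is not None else [0] * len(intervals)
    with open(path, "w") as fh:
        for iv, name, score in zip(intervals, names, scores):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score:g}\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# Windows and coverage
# ---------------------------------------------------------------------------

def tss_window(t: TranscriptModel, flank: int = 500) -> GenomicInterval:
    """Strand-aware TSS window [TSS - flank, TSS + flank), clipped at 0."""
    if flank < 0:
        raise ValueError("flank must be >= 0")
    lo = max(0, t.tss - flank)
    hi = t.tss + flank
    if flank == 0:
        hi = t.tss + 1
    return GenomicInterval(t.chrom, lo, hi, t.strand)


def count_in_window(track: ReadTrack, window: GenomicInterval) -> float:
    """Reads overlapping the window by >= 1 bp, in reads per million mapped."""
    return track.count_overlaps(window) * 1e6 / track.total_mapped


def count_per_gene(
    reads: Sequence[GenomicInterval], models: Sequence[TranscriptModel]
) -> dict[str, int]:
    """Union-mode exon counting: a read overlapping the exon union of exactly
    one gene counts for that gene; a read touching two genes' exons is
    ambiguous and counts for neither."""
    if not models:
        raise ValueError("no transcript models supplied")
    # exon table per chromosome, merged per gene
    exon_rows: dict[str, list[tuple[int, int, str]]] = {}
    gene_ids: list[str] = []
    seen = set()
    for t in models:
        if t.gene_id not in seen:
            seen.add(t.gene_id)
            gene_ids.append(t.gene_id)
        for ex in t.exons:
            exon_rows.setdefault(t.chrom, []).append((ex.start, ex.end, t.gene_id))
    index: dict[str, tuple[np.ndarray, np.ndarray, list[str]]] = {}
    for chrom, rows in exon_rows.items():
        rows.sort()
        starts = np.array([r[0] for r in rows], dtype=np.int64)
        ends = np.array([r[1] for r in rows], dtype=np.int64)
        cummax_end = np.maximum.accumulate(ends)
        index[chrom] = (starts, cummax_end, rows)

    counts = {g: 0 for g in gene_ids}
    for r in reads:
        if r.chrom not in index:
            continue
        starts, cummax_end, rows = index[r.chrom]
        hi = int(np.searchsorted(starts, r.end, side="left"))
        # walk left while any exon to the left could still reach r.start
        lo = int(np.searchsorted(cummax_end[:hi], r.start, side="right"))
        hit_genes = {
            rows[i][2] for i in range(lo, hi) if rows[i][1] > r.start and rows[i][0] < r.end
        }
        if len(hit_genes) == 1:
            counts[hit_genes.pop()] += 1
    return counts


# ---------------------------------------------------------------------------
# Neighbor pairing
# ---------------------------------------------------------------------------

def _gene_level_tss(models: Sequence[TranscriptModel]) -> dict[str, tuple[str, int, str]]:
    """5'-most TSS per gene: (chrom, tss, strand)."""
    per_gene: dict[str, tuple[str, int, str]] = {}
    for t in models:
        cur = per_gene.get(t.gene_id)
        if cur is None:
            per_gene[t.gene_id] = (t.chrom, t.tss, t.strand)
        else:
            _, cur_tss, _ = cur
            better = t.tss < cur_tss if t.strand == "+" else t.tss > cur_tss
            if better:
                per_gene[t.gene_id] = (t.chrom, t.tss, t.strand)
    return per_gene


def closest_tss(
    lincs: Sequence[TranscriptModel],
    pcs: Sequence[TranscriptModel],
    fpkm_min: float = 1.0,
) -> list[NeighborPair]:
    """Pair each lincRNA gene with the expressed protein-coding gene whose TSS
    is nearest on the same chromosome.

    Protein-coding genes qualify with FPKM > ``fpkm_min`` in at least one
    condition. Equidistant candidates resolve toward the gene downstream of
    the lincRNA (in its direction of transcription), then by gene id.
    """
    if not lincs or not pcs:
        raise ValueError("both transcript sets must be non-empty")
    expressed = {}
    for t in pcs:
        if t.max_fpkm() > fpkm_min:
            expressed[t.gene_id] = True
    pc_tss = {
        g: v for g, v in _gene_level_tss(pcs).items() if g in expressed
    }
    by_chrom: dict[str, list[tuple[int, str]]] = {}
    for g, (chrom, tss, _s) in pc_tss.items():
        by_chrom.setdefault(chrom, []).append((tss, g))
    for chrom in by_chrom:
        by_chrom[chrom].sort()

    pairs = []
    for g, (chrom, tss, strand) in sorted(_gene_level_tss(lincs).items()):
        cands = by_chrom.get(chrom)
        if not cands:
            continue
        positions = [c[0] for c in cands]
        i = int(np.searchsorted(positions, tss))
        best: tuple[int, int, str] | None = None  # (distance, tiebreak, gene)
        for j in (i - 1, i, i + 1):
            if 0 <= j < len(cands):
                p_tss, p_gene = cands[j]
                d = abs(p_tss - tss)
                downstream = (p_tss >= tss) if strand == "+" else (p_tss <= tss)
                key = (d, 0 if downstream else 1, p_gene)
                if best is None or key < best:
                    best = key
        if best is not None:
            d, tiebreak, p_gene = best
            pairs.append(
                NeighborPair(
                    lincrna_id=g,
                    pc_id=p_gene,
                    tss_distance=d,
                    orientation="downstream" if tiebreak == 0 else "upstream",
                )
            )
    return pairs


# ---------------------------------------------------------------------------
# Novel-lincRNA catalog
# ---------------------------------------------------------------------------

_IUPAC = set("ACGTURYSWKMBDHVN")

_STOPS = {"TAA", "TAG", "TGA"}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def longest_orf(sequence: str) -> int:
    """Longest open reading frame over all six frames, in codons.

    An ORF runs from an ATG to the first in-frame stop (stop excluded) or to
    the end of the frame; length counts the ATG codon.
    """
    seq = sequence.upper().replace("U", "T")
    bad = set(seq) - _IUPAC
    if bad:
        raise ValueError(f"non-IUPAC symbols in sequence: {sorted(bad)}")
    best = 0
    for s in (seq, seq.translate(_COMPLEMENT)[::-1]):
        for frame in range(3):
            codons = [s[i : i + 3] for i in range(frame, len(s) - 2, 3)]
            start = None
            for k, codon in enumerate(codons):
                if codon in _STOPS:
                    if start is not None:
                        best = max(best, k - start)
                        start = None
                elif codon == "ATG" and start is None:
                    start = k
            if start is not None:
                best = max(best, len(codons) - start)
    return best


def coding_filter(
    sequence: str | None = None,
    orf_aa: int | None = None,
    min_orf: int = 100,
) -> str:
    """Classify a transcript as 'coding' iff its longest ORF is >= ``min_orf``
    codons. Accepts a nucleotide sequence or a precomputed ORF length."""
    if orf_aa is None:
        if sequence is None:
            raise ValueError("need a sequence or a precomputed ORF length")
        orf_aa = longest_orf(sequence)
    return "coding" if orf_aa >= min_orf else "noncoding"


def _exonic_overlap(t: TranscriptModel, reference: Sequence[TranscriptModel]) -> bool:
    for r in reference:
        if r.chrom != t.chrom:
            continue
        for ex in t.exons:
            for rex in r.exons:
                if ex.start < rex.end and rex.start < ex.end:
                    return True
    return False


def classify_novel_lincrnas(
    assembled: Sequence[TranscriptModel],
    reference: Sequence[TranscriptModel],
    orf_aa: Mapping[str, int] | None = None,
    min_fpkm: float = 1.0,
    min_length: int = 200,
    min_orf: int = 100,
) -> dict[str, str]:
    """Catalog assembled transcripts as known lincRNAs or novel intergenic ones.

    Known: reference-annotated lincRNAs with FPKM >= ``min_fpkm``. Novel:
    no exonic overlap with any reference transcript (either strand),
    FPKM >= ``min_fpkm``, length >= ``min_length`` nt and non-coding by the
    longest-ORF filter (``orf_aa`` supplies per-transcript ORF lengths;
    transcripts without one are taken as non-coding).
    """
    ref_linc_ids = {r.id for r in reference if r.biotype == "lincRNA"}
    catalog: dict[str, str] = {}
    for t in assembled:
        if t.max_fpkm() < min_fpkm:
            continue
        if t.id in ref_linc_ids:
            catalog[t.id] = "known_lincRNA"
            continue
        if t.length < min_length:
            continue
        if _exonic_overlap(t, reference):
            continue
        aa = orf_aa.get(t.id) if orf_aa else None
        if aa is not None and coding_filter(orf_aa=aa, min_orf=min_orf) == "coding":
            continue
        catalog[t.id] = "novel_lincRNA"
    return catalog
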