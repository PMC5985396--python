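"""Synthetic study generator with known ground truth.

Generates a toy genome of paired lincRNA / protein-coding loci, epigenetic
read tracks with planted TSS enrichment, RIP-seq counts with a planted
AR-associated subset, RNA-seq counts with planted androgen responses that can
be coupled to the neighboring protein-coding gene, FPKM values and a TAD
partition. Everything is deterministic under the config seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .count_model import CountMatrix
from .genome_intervals import (
    GenomicInterval,
    ReadTrack,
    TranscriptModel,
    read_bed,
    read_gtf,
    write_bed,
    write_gtf,
)
from .tad_profile import Tad

__all__ = ["StudyConfig", "SyntheticStudy", "generate_study", "write_study", "read_study"]

READ_LENGTH = 75
MIN_PC_GAP = 5_000        # lincRNA locus clearance from protein-coding loci
MIN_PAIR_DISTANCE = 9_000  # TSS-to-TSS floor that guarantees MIN_PC_GAP
_CANONICAL_MARKS = ["H3K27ac", "H3K27me3", "H3K4me1", "PolII", "DNaseI"]

RIP_SAMPLES = {"antiAR_1": "antiAR", "antiAR_2": "antiAR", "IgG_1": "IgG", "IgG_2": "IgG"}
RNASEQ_SAMPLES = {
    "androgen_1": "androgen",
    "androgen_2": "androgen",
    "vehicle_1": "vehicle",
    "vehicle_2": "vehicle",
}


def default_mark_names(n_marks: int) -> list[str]:
    names = _CANONICAL_MARKS[:n_marks]
    names += [f"mark{i}" for i in range(len(names) + 1, n_marks + 1)]
    return names


def default_mark_targets(mark_names: Sequence[str]) -> dict[str, str]:
    """Which TSS set each mark is enriched at: 'ara', 'linc', 'all', 'pc' or 'none'."""
    targets = {m: "none" for m in mark_names}
    for m in ("H3K27ac", "H3K4me1"):
        if m in targets:
            targets[m] = "ara"
    for m in ("PolII", "DNaseI"):
        if m in targets:
            targets[m] = "all"
    return targets


@dataclass
class StudyConfig:
    """Knobs of the synthetic study; every planted effect is recoverable."""

    seed: int = 0
    n_chrom: int = 4
    chrom_length: int = 20_000_000
    n_lincrna: int = 1000
    n_pc: int = 1000
    n_marks: int = 5
    frac_ara: float = 0.2
    rip_log2fc_mean: float = 2.0
    rip_log2fc_sd: float = 0.25
    rnaseq_log2fc_sd: float = 0.25
    androgen_log2fc: float = 2.0
    nb_dispersion: float = 0.05
    mark_enrichment_fold: float = 8.0
    reads_per_track: int = 200_000
    n_tads: int = 40                      # per chromosome
    min_tad_length: int = 200_000
    neighbor_coupling: float = 0.7
    # probability an ARA (resp. non-ARA) lincRNA has a planted androgen response
    frac_responsive_ara: float = 0.6
    frac_responsive_other: float = 0.2
    # extra log2 activation copied to neighbors of ARA lincRNAs (0 = pure copy)
    ara_neighbor_boost: float = 0.0
    # FPKM multiplier (log2) for protein-coding partners of ARA lincRNAs
    ara_pc_fpkm_boost: float = 0.0
    # optional fixed TSS-to-TSS pair distances (bp); None = uniform draw
    ara_pair_distance: int | None = None
    other_pair_distance: int | None = None
    # restrict fold-change coupling to lincRNAs with enriched enhancer marks
    couple_only_marked: bool = False
    # place TAD boundaries adjacent to ARA lincRNA TSSs
    ara_near_tad_boundaries: bool = False
    mark_targets: dict[str, str] | None = None
    tss_flank: int = 500

    def validate(self) -> None:
        for name in ("n_chrom", "n_lincrna", "n_pc", "n_marks", "reads_per_track", "n_tads"):
            if getattr(self, name) < 1:
                raise ValueError(f"config.{name} must be >= 1")
        if not (0.0 <= self.frac_ara <= 1.0):
            raise ValueError("config.frac_ara must lie in [0, 1]")
        if not (0.0 <= self.neighbor_coupling <= 1.0):
            raise ValueError("config.neighbor_coupling must lie in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ValueError("config.nb_dispersion must be > 0")
        if self.mark_enrichment_fold < 1:
            raise ValueError("config.mark_enrichment_fold must be >= 1")
        if self.chrom_length < 10 * 3000:
            raise ValueError("config.chrom_length too small for the gene model")
        if self.n_tads * self.min_tad_length > self.chrom_length:
            raise ValueError("config.n_tads * min_tad_length exceeds chrom_length")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "StudyConfig":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class SyntheticStudy:
    config: StudyConfig
    annotation: list[TranscriptModel]
    tracks: list[ReadTrack]
    rip_counts: CountMatrix
    rnaseq_counts: CountMatrix
    fpkm: pd.DataFrame              # index gene_id, columns androgen/vehicle
    tads: list[Tad]
    truth: pd.DataFrame             # index lincrna gene_id
    chrom_names: list[str] = field(default_factory=list)

    @property
    def lincs(self) -> list[TranscriptModel]:
        return [t for t in self.annotation if t.biotype == "lincRNA"]

    @property
    def pcs(self) -> list[TranscriptModel]:
        return [t for t in self.annotation if t.biotype == "protein_coding"]


def _make_gene(
    rng: np.random.Generator,
    chrom: str,
    start: int,
    gene_id: str,
    tx_id: str,
    biotype: str,
    strand: str,
) -> TranscriptModel:
    if biotype == "protein_coding":
        n_exons = int(rng.integers(2, 4))
        exon_len = int(rng.integers(400, 900))
        intron_len = int(rng.integers(300, 700))
    else:
        n_exons = int(rng.integers(1, 3))
        exon_len = int(rng.integers(300, 1200))
        intron_len = int(rng.integers(200, 600))
    exons = []
    pos = start
    for _ in range(n_exons):
        exons.append(GenomicInterval(chrom, pos, pos + exon_len, strand))
        pos += exon_len + intron_len
    return TranscriptModel(
        id=tx_id, gene_id=gene_id, chrom=chrom, strand=strand, exons=exons, biotype=biotype
    )


def _place_annotation(cfg: StudyConfig, rng: np.random.Generator):
    """Lay out paired pc/linc loci in fixed-width blocks along each chromosome."""
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chrom)]
    n_pairs = min(cfg.n_lincrna, cfg.n_pc)
    n_extra_linc = cfg.n_lincrna - n_pairs
    n_extra_pc = cfg.n_pc - n_pairs
    total_blocks = n_pairs + n_extra_linc + n_extra_pc
    blocks_per_chrom = -(-total_blocks // cfg.n_chrom)
    block_w = cfg.chrom_length // blocks_per_chrom
    max_fixed = max(cfg.ara_pair_distance or 0, cfg.other_pair_distance or 0)
    if block_w < max(MIN_PAIR_DISTANCE + 12_000, max_fixed + 12_000):
        raise ValueError(
            "config.chrom_length too small: "
            f"{blocks_per_chrom} loci per chromosome leave only {block_w} bp each"
        )
    max_draw = min(40_000, block_w - 10_000)

    # ARA flags drawn before placement so distances can depend on them
    n_ara = int(round(cfg.frac_ara * cfg.n_lincrna))
    ara_idx = set(rng.choice(cfg.n_lincrna, size=n_ara, replace=False).tolist())

    lincs: list[TranscriptModel] = []
    pcs: list[TranscriptModel] = []
    partner: dict[str, str] = {}   # linc gene -> pc gene
    block_kinds = ["pair"] * n_pairs + ["linc"] * n_extra_linc + ["pc"] * n_extra_pc
    li = pi = 0
    for b, kind in enumerate(block_kinds):
        chrom = chroms[b % cfg.n_chrom]
        block_start = (b // cfg.n_chrom) * block_w
        anchor = block_start + 2_000
        if kind in ("pair", "pc"):
            gid, tid = f"pc{pi:05d}", f"pc{pi:05d}.1"
            pcs.append(_make_gene(rng, chrom, anchor, gid, tid, "protein_coding",
                                  "+" if rng.random() < 0.5 else "-"))
            pi += 1
        if kind in ("pair", "linc"):
            gid, tid = f"linc{li:05d}", f"linc{li:05d}.1"
            if kind == "pair":
                fixed = cfg.ara_pair_distance if li in ara_idx else cfg.other_pair_distance
                if fixed is not None:
                    d = max(int(fixed), MIN_PAIR_DISTANCE)
                else:
                    d = int(rng.integers(MIN_PAIR_DISTANCE, max_draw))
                d = min(d, block_w - 8_000)
                start = anchor + d
                partner[gid] = pcs[-1].gene_id
            else:
                start = anchor
            lincs.append(_make_gene(rng, chrom, start, gid, tid, "lincRNA",
                                    "+" if rng.random() < 0.5 else "-"))
            li += 1
    return chroms, lincs, pcs, partner, sorted(f"linc{i:05d}" for i in ara_idx)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    r = 1.0 / dispersion
    return rng.negative_binomial(r, r / (r + mean))


def _sample_track(
    rng: np.random.Generator,
    mark: str,
    chroms: Sequence[str],
    chrom_length: int,
    n_reads: int,
    windows: list[GenomicInterval],
    fold: float,
) -> ReadTrack:
    """Uniform background plus fold-enriched pileup inside the target windows;
    exactly ``n_reads`` fixed-length reads."""
    genome = len(chroms) * chrom_length
    w_total = sum(len(w) for w in windows)
    if fold > 1 and w_total > 0:
        p_win = fold * w_total / (genome - w_total + fold * w_total)
    else:
        p_win = w_total / genome if w_total else 0.0
    n_win = int(rng.binomial(n_reads, p_win)) if p_win > 0 else 0
    n_bg = n_reads - n_win

    reads: list[GenomicInterval] = []
    if n_bg:
        flat = rng.integers(0, genome, size=n_bg)
        for pos in np.sort(flat):
            ci, off = divmod(int(pos), chrom_length)
            end = min(off + READ_LENGTH, chrom_length)
            off = min(off, end - 1)
            reads.append(GenomicInterval(chroms[ci], off, end))
    if n_win:
        lengths = np.array([len(w) for w in windows], dtype=float)
        which = rng.choice(len(windows), size=n_win, p=lengths / lengths.sum())
        # focal pileup: read starts cluster around the window center the way
        # ChIP fragments cluster around a binding site
        offs = np.clip(rng.normal(0.5, 0.15, size=n_win), 0.0, 1.0 - 1e-9)
        for wi, u in zip(which, offs):
            w = windows[wi]
            start = w.start + int(u * len(w))
            end = min(start + READ_LENGTH, chrom_length)
            start = min(start, end - 1)
            reads.append(GenomicInterval(w.chrom, start, end))
    return ReadTrack(mark=mark, reads=reads, total_mapped=n_reads)


def _make_tads(
    cfg: StudyConfig, rng: np.random.Generator, chroms: Sequence[str],
    ara_tss: Mapping[str, list[int]],
) -> list[Tad]:
    tads: list[Tad] = []
    k = 0
    for chrom in chroms:
        n = cfg.n_tads
        if cfg.ara_near_tad_boundaries and ara_tss.get(chrom):
            cand = sorted({t + int(rng.integers(500, 5_000)) for t in ara_tss[chrom]})
            bounds = [0]
            for c in cand:
                if c - bounds[-1] >= cfg.min_tad_length and c < cfg.chrom_length - cfg.min_tad_length:
                    bounds.append(c)
            bounds.append(cfg.chrom_length)
        else:
            free = cfg.chrom_length - n * cfg.min_tad_length
            cuts = np.sort(rng.random(n - 1)) * free
            lengths = np.diff(np.concatenate([[0.0], cuts, [float(free)]]))
            lengths = (lengths + cfg.min_tad_length).astype(np.int64)
            lengths[-1] += cfg.chrom_length - int(lengths.sum())
            bounds = np.concatenate([[0], np.cumsum(lengths)]).tolist()
        for a, b in zip(bounds, bounds[1:]):
            tads.append(Tad(GenomicInterval(chrom, int(a), int(b)), f"tad{k:05d}"))
            k += 1
    return tads


def generate_study(config: StudyConfig) -> SyntheticStudy:
    """Build the complete synthetic study described by ``config``."""
    config.validate()
    # independent named substreams so stages stay decoupled under one seed
    seq = np.random.SeedSequence(config.seed)
    streams = dict(
        zip(
            ["layout", "rip", "rnaseq", "tracks", "tads"],
            (np.random.default_rng(s) for s in seq.spawn(5)),
        )
    )
    chroms, lincs, pcs, partner, ara_ids = _place_annotation(config, streams["layout"])
    annotation = pcs + lincs
    linc_ids = [t.gene_id for t in lincs]
    pc_ids = [t.gene_id for t in pcs]
    ara_set = set(ara_ids)
    by_gene = {t.gene_id: t for t in annotation}

    # --- RIP-seq counts (lincRNAs only) -----------------------------------
    rng = streams["rip"]
    n_l = len(linc_ids)
    base = rng.lognormal(np.log(100.0), 0.7, n_l)
    rip_lfc = np.array(
        [
            rng.normal(config.rip_log2fc_mean, config.rip_log2fc_sd)
            if g in ara_set
            else 0.0
            for g in linc_ids
        ]
    )
    mu_anti = base * 2.0**rip_lfc
    mu_igg = base
    rip = np.column_stack(
        [
            _nb_draw(rng, mu_anti, config.nb_dispersion),
            _nb_draw(rng, mu_anti, config.nb_dispersion),
            _nb_draw(rng, mu_igg, config.nb_dispersion),
            _nb_draw(rng, mu_igg, config.nb_dispersion),
        ]
    )
    rip_counts = CountMatrix(
        gene_ids=list(linc_ids),
        sample_ids=list(RIP_SAMPLES),
        counts=rip,
        condition=dict(RIP_SAMPLES),
    )

    # --- marks / tracks ----------------------------------------------------
    mark_names = default_mark_names(config.n_marks)
    targets = dict(config.mark_targets or default_mark_targets(mark_names))
    flank = config.tss_flank

    def window_of(t: TranscriptModel) -> GenomicInterval:
        lo = max(0, t.tss - flank)
        return GenomicInterval(t.chrom, lo, min(t.tss + flank, config.chrom_length))

    target_windows: dict[str, list[GenomicInterval]] = {}
    enriched_lincs: dict[str, set[str]] = {}
    for mark in mark_names:
        tgt = targets.get(mark, "none")
        if config.mark_enrichment_fold <= 1 or tgt == "none":
            target_windows[mark] = []
            enriched_lincs[mark] = set()
            continue
        if tgt == "ara":
            models = [by_gene[g] for g in ara_ids]
        elif tgt == "linc":
            models = lincs
        elif tgt == "pc":
            models = pcs
        elif tgt == "all":
            models = annotation
        else:
            raise ValueError(f"unknown mark target {tgt!r} for {mark}")
        target_windows[mark] = [window_of(t) for t in models]
        enriched_lincs[mark] = {t.gene_id for t in models if t.biotype == "lincRNA"}

    track_rng = streams["tracks"]
    tracks = [
        _sample_track(
            np.random.default_rng(track_rng.integers(2**63)),
            mark,
            chroms,
            config.chrom_length,
            config.reads_per_track,
            target_windows[mark],
            config.mark_enrichment_fold,
        )
        for mark in mark_names
    ]

    # --- RNA-seq counts and FPKM ------------------------------------------
    rng = streams["rnaseq"]
    genes = pc_ids + linc_ids
    n_g = len(genes)
    base_expr = np.concatenate(
        [rng.lognormal(np.log(300.0), 0.8, len(pc_ids)),
         rng.lognormal(np.log(60.0), 0.9, len(linc_ids))]
    )
    enhancer_marked = enriched_lincs.get("H3K27ac", set()) | enriched_lincs.get(
        "H3K4me1", set()
    )
    lfc = np.zeros(n_g)
    responsive: dict[str, float] = {}
    for g in linc_ids:
        p_resp = config.frac_responsive_ara if g in ara_set else config.frac_responsive_other
        if rng.random() < p_resp:
            sign = 1.0 if rng.random() < 0.7 else -1.0
            responsive[g] = sign * config.androgen_log2fc + rng.normal(
                0.0, config.rnaseq_log2fc_sd
            )
    coupled: set[str] = set()
    for g, val in responsive.items():
        if config.couple_only_marked and g not in enhancer_marked:
            continue
        if rng.random() < config.neighbor_coupling and g in partner:
            coupled.add(g)
    idx = {g: i for i, g in enumerate(genes)}
    for g, val in responsive.items():
        lfc[idx[g]] = val
    for g in coupled:
        boost = config.ara_neighbor_boost if g in ara_set else 0.0
        noise = rng.normal(0.0, config.rnaseq_log2fc_sd) if config.rnaseq_log2fc_sd else 0.0
        lfc[idx[partner[g]]] = responsive[g] + boost + noise

    mu_veh = base_expr
    mu_and = base_expr * 2.0**lfc
    rna = np.column_stack(
        [
            _nb_draw(rng, mu_and, config.nb_dispersion),
            _nb_draw(rng, mu_and, config.nb_dispersion),
            _nb_draw(rng, mu_veh, config.nb_dispersion),
            _nb_draw(rng, mu_veh, config.nb_dispersion),
        ]
    )
    rnaseq_counts = CountMatrix(
        gene_ids=genes,
        sample_ids=list(RNASEQ_SAMPLES),
        counts=rna,
        condition=dict(RNASEQ_SAMPLES),
    )

    lengths = np.array([by_gene[g].length for g in genes], dtype=float)
    fpkm_boost = np.ones(n_g)
    if config.ara_pc_fpkm_boost:
        for g in ara_set:
            if g in partner:
                fpkm_boost[idx[partner[g]]] = 2.0**config.ara_pc_fpkm_boost
    fpkm = pd.DataFrame(
        {
            "androgen": 1e9 * mu_and * fpkm_boost / (lengths * mu_and.sum()),
            "vehicle": 1e9 * mu_veh * fpkm_boost / (lengths * mu_veh.sum()),
        },
        index=pd.Index(genes, name="gene_id"),
    )
    for t in annotation:
        t.fpkm = {
            "androgen": float(fpkm.at[t.gene_id, "androgen"]),
            "vehicle": float(fpkm.at[t.gene_id, "vehicle"]),
        }

    # --- TADs --------------------------------------------------------------
    ara_tss: dict[str, list[int]] = {}
    for g in ara_ids:
        t = by_gene[g]
        ara_tss.setdefault(t.chrom, []).append(t.tss)
    tads = _make_tads(config, streams["tads"], chroms, ara_tss)

    # --- truth table --------------------------------------------------------
    truth = pd.DataFrame(
        {
            "is_ara": [g in ara_set for g in linc_ids],
            "is_responsive": [g in responsive for g in linc_ids],
            "is_androgen_up": [responsive.get(g, 0.0) > 0 for g in linc_ids],
            "planted_log2fc": [responsive.get(g, 0.0) for g in linc_ids],
            "rip_log2fc": rip_lfc,
            "neighbor_coupled": [g in coupled for g in linc_ids],
            "partner": [partner.get(g, "") for g in linc_ids],
            "enriched_marks": [
                ",".join(m for m in mark_names if g in enriched_lincs[m])
                for g in linc_ids
            ],
        },
        index=pd.Index(linc_ids, name="lincrna_id"),
    )

    return SyntheticStudy(
        config=config,
        annotation=annotation,
        tracks=tracks,
        rip_counts=rip_counts,
        rnaseq_counts=rnaseq_counts,
        fpkm=fpkm,
        tads=tads,
        truth=truth,
        chrom_names=chroms,
    )


# ---------------------------------------------------------------------------
# On-disk round trip
# ---------------------------------------------------------------------------

def write_study(study: SyntheticStudy, directory: str | Path) -> dict[str, Path]:
    """Write the study as plain-text files that round-trip through the readers."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    (d / "tracks").mkdir(exist_ok=True)
    paths: dict[str, Path] = {}

    paths["config"] = d / "config.json"
    study.config.to_json(paths["config"])

    paths["annotation"] = d / "annotation.gtf"
    write_gtf(study.annotation, paths["annotation"])

    manifest = []
    for tr in study.tracks:
        p = d / "tracks" / f"{tr.mark}.bed"
        write_bed(tr.reads, p)
        manifest.append({"mark": tr.mark, "path": f"tracks/{tr.mark}.bed",
                         "total_mapped": tr.total_mapped})
    paths["track_manifest"] = d / "tracks" / "manifest.tsv"
    pd.DataFrame(manifest).to_csv(paths["track_manifest"], sep="\t", index=False)

    paths["rip_counts"] = d / "rip_counts.tsv"
    study.rip_counts.to_tsv(paths["rip_counts"])
    (d / "rip_conditions.json").write_text(json.dumps(study.rip_counts.condition) + "\n")

    paths["rnaseq_counts"] = d / "rnaseq_counts.tsv"
    study.rnaseq_counts.to_tsv(paths["rnaseq_counts"])
    (d / "rnaseq_conditions.json").write_text(
        json.dumps(study.rnaseq_counts.condition) + "\n"
    )

    paths["fpkm"] = d / "fpkm.tsv"
    study.fpkm.to_csv(paths["fpkm"], sep="\t")

    paths["tads"] = d / "tads.bed"
    write_bed([t.interval for t in study.tads], paths["tads"],
              names=[t.id for t in study.tads])

    paths["truth"] = d / "truth.tsv"
    study.truth.to_csv(paths["truth"], sep="\t")
    return paths


def read_study(directory: str | Path) -> SyntheticStudy:
    """Read back a study written by :func:`write_study`."""
    d = Path(directory)
    config = StudyConfig.from_json(d / "config.json")
    annotation = read_gtf(d / "annotation.gtf")
    manifest = pd.read_csv(d / "tracks" / "manifest.tsv", sep="\t")
    tracks = [
        ReadTrack(
            mark=row["mark"],
            reads=read_bed(d / row["path"]),
            total_mapped=int(row["total_mapped"]),
        )
        for _, row in manifest.iterrows()
    ]
    rip_counts = CountMatrix.from_tsv(
        d / "rip_counts.tsv", json.loads((d / "rip_conditions.json").read_text())
    )
    rnaseq_counts = CountMatrix.from_tsv(
        d / "rnaseq_counts.tsv", json.loads((d / "rnaseq_conditions.json").read_text())
    )
    fpkm = pd.read_csv(d / "fpkm.tsv", sep="\t", index_col=0)
    tad_ivs = read_bed(d / "tads.bed")
    with open(d / "tads.bed") as fh:
        tad_ids = [line.split("\t")[3] for line in fh if line.strip()]
    tads = [Tad(iv, tid) for iv, tid in zip(tad_ivs, tad_ids)]
    truth = pd.read_csv(d / "truth.tsv", sep="\t", index_col=0, keep_default_na=False,
                        converters={"enriched_marks": str})
    chroms = sorted({t.chrom for t in annotation}, key=lambda c: int(c.lstrip("chr")))
    return SyntheticStudy(
        config=config,
        annotation=annotation,
        tracks=tracks,
        rip_counts=rip_counts,
        rnaseq_counts=rnaseq_counts,
        fpkm=fpkm,
        tads=tads,
        truth=truth,
        chrom_names=chroms,
    )
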