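import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from arasig.genome_intervals import (
    GenomicInterval,
    NeighborPair,
    ReadTrack,
    TranscriptModel,
    classify_novel_lincrnas,
    closest_tss,
    coding_filter,
    count_in_window,
    count_per_gene,
    longest_orf,
    read_gtf,
    tss_window,
    write_gtf,
)


def make_tx(tid, chrom, exon_coords, strand="+", biotype="lincRNA", fpkm=None, gene=None):
    return TranscriptModel(
        id=tid,
        gene_id=gene or tid.split(".")[0],
        chrom=chrom,
        strand=strand,
        exons=[GenomicInterval(chrom, a, b, strand) for a, b in exon_coords],
        biotype=biotype,
        fpkm=fpkm or {},
    )


class TestGenomicInterval:
    def test_rejects_inverted(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 10, 10)

    def test_overlap_half_open(self):
        a = GenomicInterval("chr1", 0, 10)
        assert not a.overlaps(GenomicInterval("chr1", 10, 20))
        assert a.overlaps(GenomicInterval("chr1", 9, 20))
        assert not a.overlaps(GenomicInterval("chr2", 0, 10))


class TestGtfIO:
    def test_coordinate_conversion(self, tmp_path):
        p = tmp_path / "x.gtf"
        p.write_text(
            'chr1\tsrc\texon\t101\t200\t.\t+\t.\tgene_id "g1"; transcript_id "t1";\n'
        )
        (tx,) = read_gtf(p)
        assert tx.exons[0].start == 100 and tx.exons[0].end == 200

    def test_round_trip(self, tmp_path, study):
        p = tmp_path / "ann.gtf"
        write_gtf(study.annotation, p)
        back = read_gtf(p)
        assert len(back) == len(study.annotation)
        orig = {t.id: t for t in study.annotation}
        for t in back:
            o = orig[t.id]
            assert [(e.start, e.end) for e in t.exons] == [
                (e.start, e.end) for e in o.exons
            ]
            assert (t.strand, t.biotype, t.gene_id) == (o.strand, o.biotype, o.gene_id)
            assert t.fpkm.keys() == o.fpkm.keys()
            for k in t.fpkm:
                assert t.fpkm[k] == pytest.approx(o.fpkm[k], rel=1e-5)

    def test_mixed_strand_rejected(self, tmp_path):
        p = tmp_path / "bad.gtf"
        p.write_text(
            'chr1\ts\texon\t1\t50\t.\t+\t.\tgene_id "g"; transcript_id "t";\n'
            'chr1\ts\texon\t100\t150\t.\t-\t.\tgene_id "g"; transcript_id "t";\n'
        )
        with pytest.raises(ValueError, match="mixed strand"):
            read_gtf(p)

    def test_malformed_line_reports_number(self, tmp_path):
        p = tmp_path / "bad.gtf"
        p.write_text("chr1\tonly\tthree\n")
        with pytest.raises(ValueError, match=":1"):
            read_gtf(p)

    def test_unknown_strand_rejected(self, tmp_path):
        p = tmp_path / "bad.gtf"
        p.write_text('chr1\ts\texon\t1\t50\t.\t*\t.\tgene_id "g"; transcript_id "t";\n')
        with pytest.raises(ValueError, match="strand"):
            read_gtf(p)


class TestTssWindow:
    def test_plus_strand(self):
        t = make_tx("t1", "chr1", [(5000, 6000)])
        w = tss_window(t, 500)
        assert (w.start, w.end) == (4500, 5500)

    def test_clipped_at_zero(self):
        t = make_tx("t1", "chr1", [(200, 900)])
        w = tss_window(t, 500)
        assert (w.start, w.end) == (0, 700)

    def test_minus_strand_uses_rightmost(self):
        t = make_tx("t1", "chr1", [(7000, 8000), (8500, 9000)], strand="-")
        # exhaustive exon-scan oracle: TSS is the max end minus one on '-'
        oracle_tss = max(e.end for e in t.exons) - 1
        w = tss_window(t, 500)
        assert w.start == oracle_tss - 500 and w.end == oracle_tss + 500

    def test_negative_flank_rejected(self):
        with pytest.raises(ValueError):
            tss_window(make_tx("t", "chr1", [(0, 10)]), -1)


class TestCountInWindow:
    def test_direct_arithmetic(self):
        reads = [GenomicInterval("chr1", 1000 + i, 1075 + i) for i in range(50)]
        track = ReadTrack("m", reads, total_mapped=1_000_000)
        w = GenomicInterval("chr1", 900, 1200)
        assert count_in_window(track, w) == pytest.approx(50.0)

    def test_empty_region(self):
        track = ReadTrack("m", [GenomicInterval("chr1", 0, 75)], total_mapped=100)
        assert count_in_window(track, GenomicInterval("chr1", 5000, 6000)) == 0.0

    def test_doubling_total_halves(self):
        reads = [GenomicInterval("chr1", 100, 175)]
        w = GenomicInterval("chr1", 0, 500)
        a = count_in_window(ReadTrack("m", reads, 1000), w)
        b = count_in_window(ReadTrack("m", reads, 2000), w)
        assert a == pytest.approx(2 * b)

    def test_one_bp_overlap_counts(self):
        track = ReadTrack("m", [GenomicInterval("chr1", 100, 175)], 100)
        assert count_in_window(track, GenomicInterval("chr1", 174, 200)) > 0
        assert count_in_window(track, GenomicInterval("chr1", 175, 200)) == 0

    def test_matches_brute_force_random(self):
        rng = np.random.default_rng(0)
        reads = [
            GenomicInterval("chr1", int(s), int(s) + int(l))
            for s, l in zip(rng.integers(0, 10_000, 500), rng.integers(30, 120, 500))
        ]
        track = ReadTrack("m", reads, 500)
        for _ in range(20):
            s = int(rng.integers(0, 9_000))
            w = GenomicInterval("chr1", s, s + int(rng.integers(50, 900)))
            brute = sum(r.overlaps(w) for r in reads)
            assert track.count_overlaps(w) == brute


class TestCountPerGene:
    def test_read_spanning_two_exons_counts_once(self):
        g = make_tx("g1.1", "chr1", [(100, 200), (250, 350)], gene="g1")
        reads = [GenomicInterval("chr1", 180, 260)]
        assert count_per_gene(reads, [g]) == {"g1": 1}

    def test_ambiguous_read_counts_for_neither(self):
        g1 = make_tx("g1.1", "chr1", [(100, 200)], gene="g1")
        g2 = make_tx("g2.1", "chr1", [(150, 300)], gene="g2")
        reads = [GenomicInterval("chr1", 140, 215)]
        assert count_per_gene(reads, [g1, g2]) == {"g1": 0, "g2": 0}

    def test_no_reads(self):
        g = make_tx("g1.1", "chr1", [(0, 100)], gene="g1")
        assert count_per_gene([], [g]) == {"g1": 0}

    def test_matches_brute_force(self):
        rng = np.random.default_rng(1)
        genes = []
        pos = 0
        for i in range(40):
            pos += int(rng.integers(200, 800))
            n_ex = int(rng.integers(1, 4))
            exons = []
            for _ in range(n_ex):
                l = int(rng.integers(80, 300))
                exons.append((pos, pos + l))
                pos += l + int(rng.integers(50, 200))
            genes.append(make_tx(f"g{i}.1", "chr1", exons, gene=f"g{i}"))
        reads = [
            GenomicInterval("chr1", int(s), int(s) + 75)
            for s in rng.integers(0, pos, 2000)
        ]
        result = count_per_gene(reads, genes)
        # brute force overlap scan
        brute = {g.gene_id: 0 for g in genes}
        for r in reads:
            hits = {
                g.gene_id
                for g in genes
                for e in g.exons
                if r.start < e.end and e.start < r.end
            }
            if len(hits) == 1:
                brute[hits.pop()] += 1
        assert result == brute


class TestClosestTss:
    def _pc(self, gene, chrom, tss, fpkm=5.0):
        return make_tx(
            f"{gene}.1", chrom, [(tss, tss + 500)], biotype="protein_coding",
            fpkm={"androgen": fpkm}, gene=gene,
        )

    def test_basic(self):
        linc = make_tx("l1.1", "chr1", [(1000, 1400)], gene="l1")
        pcs = [self._pc("p1", "chr1", 300), self._pc("p2", "chr1", 1500)]
        (pair,) = closest_tss([linc], pcs)
        assert pair.pc_id == "p2" and pair.tss_distance == 500

    def test_equidistant_tie_breaks_downstream(self):
        linc = make_tx("l1.1", "chr1", [(1000, 1400)], gene="l1")
        pcs = [self._pc("p1", "chr1", 500), self._pc("p2", "chr1", 1500)]
        (pair,) = closest_tss([linc], pcs)
        assert pair.pc_id == "p2" and pair.orientation == "downstream"

    def test_no_same_chromosome_candidate(self):
        linc = make_tx("l1.1", "chr1", [(1000, 1400)], gene="l1")
        pcs = [self._pc("p1", "chr2", 500)]
        assert closest_tss([linc], pcs) == []

    def test_unexpressed_pc_skipped(self):
        linc = make_tx("l1.1", "chr1", [(1000, 1400)], gene="l1")
        pcs = [self._pc("p1", "chr1", 900, fpkm=0.5), self._pc("p2", "chr1", 9000)]
        (pair,) = closest_tss([linc], pcs)
        assert pair.pc_id == "p2"

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(7)
        lincs, pcs = [], []
        for i in range(60):
            c = f"chr{rng.integers(1, 4)}"
            tss = int(rng.integers(0, 1_000_000))
            lincs.append(make_tx(f"l{i}.1", c, [(tss, tss + 400)], gene=f"l{i}"))
        for i in range(200):
            c = f"chr{rng.integers(1, 4)}"
            tss = int(rng.integers(0, 1_000_000))
            pcs.append(self._pc(f"p{i}", c, tss, fpkm=float(rng.uniform(0, 10))))
        pairs = {p.lincrna_id: p for p in closest_tss(lincs, pcs)}
        # O(n*m) oracle
        for l in lincs:
            best = None
            for p in pcs:
                if p.chrom != l.chrom or p.max_fpkm() <= 1.0:
                    continue
                d = abs(p.tss - l.tss)
                if best is None or d < best[0]:
                    best = (d, p.gene_id)
            if best is None:
                assert l.gene_id not in pairs
            else:
                assert pairs[l.gene_id].tss_distance == best[0]


class TestNeighborPair:
    def test_invalid_orientation(self):
        with pytest.raises(ValueError):
            NeighborPair("l", "p", 10, "sideways")

    def test_negative_distance(self):
        with pytest.raises(ValueError):
            NeighborPair("l", "p", -1, "upstream")


class TestCodingFilter:
    def test_tandem_stops_noncoding(self):
        assert coding_filter("TAATAGTGA" * 40) == "noncoding"

    def test_long_open_frame_coding(self):
        seq = "ATG" + "GCT" * 399 + "TAA"
        # six-frame brute-force oracle
        assert longest_orf(seq) == 400
        assert coding_filter(seq) == "coding"

    def test_boundary_exactly_100_codons_is_coding(self):
        assert coding_filter(orf_aa=100) == "coding"
        assert coding_filter(orf_aa=99) == "noncoding"

    def test_reverse_strand_orf_found(self):
        fwd = "ATG" + "AAA" * 150 + "TGA"
        rc = fwd.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        assert longest_orf(rc) == 151

    def test_non_iupac_rejected(self):
        with pytest.raises(ValueError):
            longest_orf("ACGTXX")

    @given(st.text(alphabet="ACGT", min_size=0, max_size=120))
    @settings(max_examples=100, deadline=None)
    def test_matches_six_frame_oracle(self, seq):
        def orf_in_frame(s):
            best = 0
            codons = [s[i : i + 3] for i in range(0, len(s) - 2, 3)]
            for start in range(len(codons)):
                if codons[start] != "ATG":
                    continue
                n = 0
                for c in codons[start:]:
                    if c in ("TAA", "TAG", "TGA"):
                        break
                    n += 1
                best = max(best, n)
            return best

        rc = seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        oracle = max(
            orf_in_frame(s[f:]) for s in (seq, rc) for f in range(3)
        ) if len(seq) >= 3 else 0
        assert longest_orf(seq) == oracle


class TestNovelCatalog:
    def _ref(self):
        return [
            make_tx("known1.1", "chr1", [(1000, 2000)], gene="known1",
                    fpkm={"androgen": 4.0}),
            make_tx("pcref.1", "chr1", [(50_000, 52_000)], biotype="protein_coding",
                    gene="pcref"),
        ]

    def test_short_transcript_removed(self):
        novel = make_tx("n1.1", "chr1", [(10_000, 10_150)], fpkm={"androgen": 5.0})
        cat = classify_novel_lincrnas([novel], self._ref())
        assert "n1.1" not in cat

    def test_low_fpkm_removed(self):
        novel = make_tx("n1.1", "chr1", [(10_000, 10_800)], fpkm={"androgen": 0.5})
        cat = classify_novel_lincrnas([novel], self._ref())
        assert "n1.1" not in cat

    def test_overlap_with_reference_exon_not_novel(self):
        novel = make_tx("n1.1", "chr1", [(51_000, 53_000)], fpkm={"androgen": 5.0})
        cat = classify_novel_lincrnas([novel], self._ref())
        assert "n1.1" not in cat
        # brute-force oracle agrees there is exonic overlap
        assert any(
            e.start < re.end and re.start < e.end
            for e in novel.exons
            for r in self._ref()
            for re in r.exons
        )

    def test_clean_intergenic_is_novel(self):
        novel = make_tx("n1.1", "chr1", [(10_000, 10_800)], fpkm={"androgen": 5.0})
        cat = classify_novel_lincrnas([novel], self._ref())
        assert cat["n1.1"] == "novel_lincRNA"

    def test_coding_novel_removed(self):
        novel = make_tx("n1.1", "chr1", [(10_000, 10_800)], fpkm={"androgen": 5.0})
        cat = classify_novel_lincrnas([novel], self._ref(), orf_aa={"n1.1": 150})
        assert "n1.1" not in cat

    def test_known_lincrna_kept(self):
        known = self._ref()[0]
        cat = classify_novel_lincrnas([known], self._ref())
        assert cat["known1.1"] == "known_lincRNA"
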