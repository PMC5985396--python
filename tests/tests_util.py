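"""Small shared builders for tests."""

from arasig.genome_intervals import GenomicInterval, ReadTrack, TranscriptModel


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


def make_track_at(mark, chrom, center, n, total, spread=50, read_len=75):
    """A track with ``n`` reads piled around ``center``."""
    reads = [
        GenomicInterval(chrom, center - spread + (i * 2 * spread) // max(n, 1),
                        center - spread + (i * 2 * spread) // max(n, 1) + read_len)
        for i in range(n)
    ]
    return ReadTrack(mark, reads, total)
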