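import math

import numpy as np
import pytest

from ribofeat import (
    Transcript,
    extract_regions,
    gc_content,
    read_transcripts,
    write_transcripts,
)
from ribofeat.transcript import normalize_sequence


def write_fasta(path, records):
    path.write_text("".join(f">{rid}\n{seq}\n" for rid, seq in records))


class TestReading:
    def test_single_record_without_annotation_is_single_exon(self, tmp_path):
        fa = tmp_path / "t.fa"
        write_fasta(fa, [("tx1", "ATGAAATAG")])
        ts = read_transcripts(fa)
        assert len(ts) == 1
        assert ts[0].exon_lengths == [9]
        assert ts[0].intron_lengths == []

    def test_bed12_blocks_give_exon_and_intron_lengths(self, tmp_path):
        fa = tmp_path / "t.fa"
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), 150))
        write_fasta(fa, [("tx1", seq)])
        bed = tmp_path / "t.bed"
        # blocks of 100 and 50 separated by a 200-nt intron
        bed.write_text("chr1\t1000\t1350\ttx1\t0\t+\t1000\t1000\t0\t2\t100,50\t0,300\n")
        t = read_transcripts(fa, bed)[0]
        assert t.exon_lengths == [100, 50]
        assert t.intron_lengths == [200]
        assert t.genome_intervals == [("chr1", 1000, 1100, "+"), ("chr1", 1300, 1350, "+")]

    def test_minus_strand_gtf_reorders_exons(self, tmp_path):
        fa = tmp_path / "t.fa"
        write_fasta(fa, [("tx1", "ACGTACGTAC")])  # 10 nt: exons 6 + 4
        gtf = tmp_path / "t.gtf"
        gtf.write_text(
            'chr1\tsrc\texon\t101\t104\t.\t-\t.\tgene_id "g1"; transcript_id "tx1";\n'
            'chr1\tsrc\texon\t205\t210\t.\t-\t.\tgene_id "g1"; transcript_id "tx1";\n'
        )
        t = read_transcripts(fa, gtf)[0]
        # transcript order on minus strand starts from the genomic-rightmost exon
        assert t.exon_lengths == [6, 4]
        assert t.intron_lengths == [100]

    def test_alphabet_normalization(self):
        assert normalize_sequence("acgu") == "ACGT"
        assert normalize_sequence("AuRr") == "ATNN"

    def test_length_mismatch_reports_both_lengths(self, tmp_path):
        fa = tmp_path / "t.fa"
        write_fasta(fa, [("tx1", "ACGT" * 10)])
        bed = tmp_path / "t.bed"
        bed.write_text("chr1\t0\t100\ttx1\t0\t+\t0\t0\t0\t1\t100\t0\n")
        with pytest.raises(ValueError, match="tx1.*100.*40|tx1.*40.*100"):
            read_transcripts(fa, bed)

    def test_empty_fasta_raises(self, tmp_path):
        fa = tmp_path / "empty.fa"
        fa.write_text("")
        with pytest.raises(ValueError, match="empty"):
            read_transcripts(fa)

    def test_fasta_bed12_round_trip(self, tmp_path, small_cohort):
        ts = small_cohort.transcripts[:10]
        write_transcripts(ts, tmp_path / "rt.fa", tmp_path / "rt.bed")
        back = read_transcripts(tmp_path / "rt.fa", tmp_path / "rt.bed")
        assert [t.id for t in back] == [t.id for t in ts]
        for a, b in zip(ts, back):
            assert a.seq == b.seq
            assert a.exon_lengths == b.exon_lengths
            assert a.intron_lengths == b.intron_lengths
            assert a.genome_intervals == b.genome_intervals


class TestGcContent:
    @pytest.mark.parametrize(
        "seq,expected",
        [("GCGC", 1.0), ("ATAT", 0.0), ("GCATN", 0.5), ("GGCCAATT", 0.5)],
    )
    def test_values(self, seq, expected):
        assert gc_content(seq) == pytest.approx(expected)

    def test_all_n_or_empty_is_missing(self):
        assert math.isnan(gc_content("NNN"))
        assert math.isnan(gc_content(""))


class TestRegions:
    def test_interior_orf_partitions(self):
        t = Transcript("x", "A" * 30)
        r = extract_regions(t, (6, 24))
        assert r.five_utr == (0, 6)
        assert r.orf == (6, 24)
        assert r.three_utr == (24, 30)

    def test_orf_at_origin_has_no_five_utr(self):
        t = Transcript("x", "A" * 30)
        r = extract_regions(t, (0, 12))
        assert r.five_utr is None
        assert r.three_utr == (12, 30)

    def test_missing_orf_yields_empty_map(self):
        t = Transcript("x", "A" * 30)
        r = extract_regions(t, None)
        assert r.five_utr is None and r.orf is None and r.three_utr is None

    def test_out_of_bounds_orf_raises(self):
        t = Transcript("x", "A" * 10)
        with pytest.raises(ValueError):
            extract_regions(t, (3, 12))

    def test_partition_covers_transcript_exactly(self):
        rng = np.random.default_rng(5)
        for _ in range(1000):
            n = int(rng.integers(10, 400))
            s = int(rng.integers(0, n - 2))
            e = int(rng.integers(s + 1, n + 1))
            t = Transcript("x", "A" * n)
            r = extract_regions(t, (s, e))
            segments = [iv for iv in (r.five_utr, r.orf, r.three_utr) if iv]
            assert segments[0][0] == 0 and segments[-1][1] == n
            for (a, b), (c, d) in zip(segments, segments[1:]):
                assert b == c
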