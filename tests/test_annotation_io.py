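"""Transcript model IO, junction extraction and junction-read counting."""

import pysam
import pytest

from juncsplice.annotation import (
    EXON_EXON,
    EXON_INTRON_3P,
    EXON_INTRON_5P,
    GtfParseError,
    Junction,
    JunctionCounts,
    ValidationError,
    count_junctions_from_alignments,
    extract_junctions,
    filter_junctions,
    read_gtf,
    read_junction_counts,
    write_gtf,
    write_junction_counts,
)

from conftest import make_transcript


class TestGtf:
    def test_coordinate_conversion_and_intron(self, tmp_path):
        """1-based inclusive GTF exons become 0-based half-open intervals."""
        gtf = tmp_path / "a.gtf"
        gtf.write_text(
            'chr1\tx\texon\t100\t200\t.\t+\t.\tgene_id "g1"; transcript_id "t1";\n'
            'chr1\tx\texon\t300\t400\t.\t+\t.\tgene_id "g1"; transcript_id "t1";\n'
        )
        (model,) = read_gtf(gtf)
        assert model.exons == ((99, 200), (299, 400))
        assert model.introns() == ((200, 299),)

    def test_missing_transcript_id_names_line(self, tmp_path):
        gtf = tmp_path / "bad.gtf"
        gtf.write_text('chr1\tx\texon\t1\t10\t.\t+\t.\tgene_id "g1";\n')
        with pytest.raises(GtfParseError, match="bad.gtf:1"):
            read_gtf(gtf)

    def test_zero_exon_transcript_rejected(self, tmp_path):
        gtf = tmp_path / "noexon.gtf"
        gtf.write_text(
            'chr1\tx\ttranscript\t1\t10\t.\t+\t.\tgene_id "g1"; transcript_id "t1";\n'
        )
        with pytest.raises(ValidationError, match="t1"):
            read_gtf(gtf)

    def test_round_trip_identity(self, tmp_path, toy_models):
        path = tmp_path / "rt.gtf"
        write_gtf(toy_models, path)
        back = read_gtf(path)
        assert {m.transcript_id: m.exons for m in back} == {
            m.transcript_id: m.exons for m in toy_models
        }
        path2 = tmp_path / "rt2.gtf"
        write_gtf(back, path2)
        assert path.read_text() == path2.read_text()

    def test_cds_round_trip(self, tmp_path):
        m = make_transcript(
            "t1", "g1", [(0, 100), (200, 300)], cds=(30, 280)
        )
        path = tmp_path / "cds.gtf"
        write_gtf([m], path)
        (back,) = read_gtf(path)
        assert back.cds == (30, 280)
        assert back.cds_segments() == ((30, 100), (200, 280))


class TestModelInvariants:
    @pytest.mark.parametrize(
        "exons",
        [
            [],  # no exon
            [(100, 50)],  # inverted interval
            [(0, 100), (100, 200)],  # adjacent (no intron gap)
            [(0, 100), (50, 200)],  # overlapping
            [(200, 300), (0, 100)],  # unsorted
        ],
    )
    def test_invalid_exon_chains_rejected(self, exons):
        with pytest.raises(ValidationError):
            make_transcript("t", "g", exons)


class TestJunctionExtraction:
    def test_one_intron_three_junctions(self):
        m = make_transcript("t", "g", [(0, 100), (200, 300)])
        juncs = extract_junctions([m])
        kinds = sorted(j.kind for j in juncs)
        assert kinds == [EXON_EXON, EXON_INTRON_3P, EXON_INTRON_5P]
        assert all((j.intron_start, j.intron_end) == (100, 200) for j in juncs)

    def test_deduplicated_across_transcripts(self):
        ms = [
            make_transcript(f"t{i}", "g", [(0, 100), (200, 300)]) for i in range(3)
        ]
        assert len(extract_junctions(ms)) == 3

    def test_single_exon_contributes_nothing(self):
        m1 = make_transcript("t1", "g", [(0, 300)])
        m2 = make_transcript("t2", "g2", [(0, 100), (200, 300)])
        assert len(extract_junctions([m1, m2])) == 3

    def test_boundary_is_strand_aware(self):
        plus = Junction("c", "+", EXON_INTRON_5P, 100, 200)
        minus = Junction("c", "-", EXON_INTRON_5P, 100, 200)
        assert plus.boundary == 100  # donor left of intron on +
        assert minus.boundary == 200  # donor right of intron on -


class TestCountsIO:
    def _counts(self):
        j1 = Junction("chr1", "+", EXON_EXON, 100, 200)
        j2 = Junction("chr1", "+", EXON_INTRON_5P, 100, 200)
        c = JunctionCounts(samples=["s1", "s2"])
        c.set(j1, "s1", 4)
        c.set(j1, "s2", 6)
        c.set(j2, "s1", 0)
        c.set(j2, "s2", 3)
        return c

    def test_round_trip_lossless(self, tmp_path):
        counts = self._counts()
        path = tmp_path / "counts.tsv"
        write_junction_counts(counts, path)
        assert read_junction_counts(path) == counts

    def test_unknown_sample_vs_design_rejected(self, tmp_path):
        path = tmp_path / "counts.tsv"
        write_junction_counts(self._counts(), path)
        with pytest.raises(ValidationError, match="s2"):
            read_junction_counts(path, design_samples=["s1"])

    def test_empty_table_is_empty_counts(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("chrom\tstrand\tkind\tintron_start\tintron_end\n")
        assert len(read_junction_counts(path)) == 0

    def test_negative_count_rejected(self, tmp_path):
        path = tmp_path / "neg.tsv"
        path.write_text(
            "chrom\tstrand\tkind\tintron_start\tintron_end\ts1\n"
            "chr1\t+\texon_exon\t100\t200\t-1\n"
        )
        with pytest.raises(ValidationError):
            read_junction_counts(path)

    @pytest.mark.parametrize(
        "per_sample,kept", [([4, 6], True), ([4, 4], False), ([5], True)]
    )
    def test_filter_max_over_samples(self, per_sample, kept):
        """Retention needs >= 5 uniquely mapped reads in at least one sample."""
        j = Junction("chr1", "+", EXON_EXON, 100, 200)
        c = JunctionCounts()
        for i, v in enumerate(per_sample):
            c.set(j, f"s{i}", v)
        assert (j in filter_junctions(c, min_reads=5)) is kept


def _write_sam(path, reads):
    header = {"HD": {"VN": "1.6"}, "SQ": [{"SN": "chr1", "LN": 10000}]}
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for name, start, cigar, nh in reads:
            a = pysam.AlignedSegment(fh.header)
            a.query_name = name
            a.query_sequence = "A" * sum(l for op, l in cigar if op in (0, 1, 4))
            a.flag = 0
            a.reference_id = 0
            a.reference_start = start
            a.mapping_quality = 50
            a.cigartuples = cigar
            a.set_tag("NH", nh)
            fh.write(a)


class TestAlignmentCounting:
    def test_gap_must_match_intron_with_overhang(self, tmp_path):
        """A 50M100N50M read starting at 10 supports the intron [60,160)."""
        sam = tmp_path / "s.sam"
        _write_sam(
            sam,
            [
                ("match", 10, [(0, 50), (3, 100), (0, 50)], 1),
                ("short_overhang", 57, [(0, 3), (3, 100), (0, 50)], 1),
                ("wrong_gap", 10, [(0, 50), (3, 99), (0, 50)], 1),
            ],
        )
        j = Junction("chr1", "+", EXON_EXON, 60, 160)
        counts = count_junctions_from_alignments({"s1": sam}, [j], min_overhang=5)
        assert counts.get(j, "s1") == 1

    def test_multimapped_reads_excluded_when_unique_only(self, tmp_path):
        sam = tmp_path / "s.sam"
        _write_sam(sam, [("multi", 10, [(0, 50), (3, 100), (0, 50)], 2)])
        j = Junction("chr1", "+", EXON_EXON, 60, 160)
        unique = count_junctions_from_alignments({"s1": sam}, [j], unique_only=True)
        loose = count_junctions_from_alignments({"s1": sam}, [j], unique_only=False)
        assert unique.get(j, "s1") == 0
        assert loose.get(j, "s1") == 1
        assert unique.qc["multimapped_excluded"] == 1

    def test_exon_intron_boundary_needs_overhang_both_sides(self, tmp_path):
        sam = tmp_path / "s.sam"
        _write_sam(
            sam,
            [
                ("spanning", 55, [(0, 20)], 1),  # 5 left / 15 right of 60
                ("too_short", 58, [(0, 6)], 1),  # 2 left / 4 right
            ],
        )
        j5 = Junction("chr1", "+", EXON_INTRON_5P, 60, 160)
        counts = count_junctions_from_alignments({"s1": sam}, [j5], min_overhang=5)
        assert counts.get(j5, "s1") == 1

    def test_planted_counts_recovered_exactly(self, tmp_path):
        """Reads constructed per-junction reproduce the planted counts."""
        juncs = [
            Junction("chr1", "+", EXON_EXON, 500, 700),
            Junction("chr1", "+", EXON_INTRON_5P, 500, 700),
            Junction("chr1", "+", EXON_INTRON_3P, 700, 900),
        ]
        planted = {juncs[0]: 7, juncs[1]: 4, juncs[2]: 3}
        reads = []
        for i in range(planted[juncs[0]]):
            reads.append((f"ee{i}", 450, [(0, 50), (3, 200), (0, 50)], 1))
        for i in range(planted[juncs[1]]):
            reads.append((f"b5{i}", 480, [(0, 40)], 1))  # spans 500
        for i in range(planted[juncs[2]]):
            reads.append((f"b3{i}", 880, [(0, 40)], 1))  # spans 900
        sam = tmp_path / "s.sam"
        _write_sam(sam, reads)
        counts = count_junctions_from_alignments({"s1": sam}, juncs, min_overhang=5)
        assert {j: counts.get(j, "s1") for j in juncs} == planted
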