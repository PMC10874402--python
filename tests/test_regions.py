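"""Coordinate engine: BED I/O, interval merging, overlap queries, gene models."""

import numpy as np
import pytest

from taslrs.errors import ParseError, ValidationError
from taslrs.regions import (
    GenomicInterval,
    RegionSet,
    read_bed,
    read_gene_annotation,
    write_bed,
)


def brute_force_union_bp(intervals, size=100_000):
    """Per-base boolean-array oracle for merged coverage."""
    mask = {}
    for iv in intervals:
        arr = mask.setdefault(iv.chrom, np.zeros(size, dtype=bool))
        arr[iv.start : iv.end] = True
    return sum(int(arr.sum()) for arr in mask.values())


class TestGenomicInterval:
    def test_invariants_rejected(self):
        with pytest.raises(ValidationError):
            GenomicInterval("chr1", 10, 10)
        with pytest.raises(ValidationError):
            GenomicInterval("chr1", -1, 5)
        with pytest.raises(ValidationError):
            GenomicInterval("", 0, 5)

    def test_one_based_round_trip(self):
        # printed 1-based inclusive coordinates convert and convert back
        iv = GenomicInterval.from_one_based("chr6", 122_847_699, 122_847_780)
        assert iv.start == 122_847_698 and iv.end == 122_847_780
        assert iv.length == 82
        assert iv.to_one_based() == ("chr6", 122_847_699, 122_847_780)

    def test_expand_clips(self):
        iv = GenomicInterval("chr1", 100, 200).expand(150, chrom_size=300)
        assert (iv.start, iv.end) == (0, 300)


class TestBedIO:
    def test_basic_line(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t0\t10\n")
        rs = read_bed(p)
        assert rs.intervals == (GenomicInterval("chr1", 0, 10),)

    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.bed"
        p.write_text("")
        rs = read_bed(p)
        assert len(rs) == 0 and rs.total_bp == 0

    def test_zero_length_record_rejected(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t10\t10\n")
        with pytest.raises(ParseError):
            read_bed(p)

    def test_malformed_line_names_line_number(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t0\t10\nchr1\toops\n")
        with pytest.raises(ParseError, match="2"):
            read_bed(p)

    def test_strand_from_six_columns(self, tmp_path):
        p = tmp_path / "s.bed"
        p.write_text("chr1\t0\t10\tx\t0\t-\nchr1\t20\t30\n")
        rs = read_bed(p)
        assert rs.intervals[0].strand == "-"
        assert rs.intervals[1].strand == "."

    def test_round_trip_normalized(self, tmp_path):
        rs = RegionSet.from_tuples([("chr1", 5, 20), ("chr2", 0, 7)]).merge()
        p = tmp_path / "rt.bed"
        write_bed(rs, p)
        again = read_bed(p)
        assert again.intervals == rs.intervals


class TestMerge:
    def test_overlap_union(self):
        rs = RegionSet.from_tuples([("chr1", 0, 10), ("chr1", 5, 15)]).merge()
        assert rs.intervals == (GenomicInterval("chr1", 0, 15),)

    def test_disjoint_identity(self):
        rs = RegionSet.from_tuples([("chr1", 0, 10), ("chr1", 20, 30)]).merge()
        assert [(iv.start, iv.end) for iv in rs.intervals] == [(0, 10), (20, 30)]

    def test_random_against_per_base_oracle(self):
        rng = np.random.default_rng(7)
        intervals = []
        for _ in range(100):
            chrom = f"chr{rng.integers(1, 4)}"
            start = int(rng.integers(0, 90_000))
            end = start + int(rng.integers(1, 5_000))
            intervals.append(GenomicInterval(chrom, start, end))
        rs = RegionSet(intervals)
        merged = rs.merge()
        assert merged.total_bp == brute_force_union_bp(intervals)
        # idempotent and order-independent
        assert merged.merge().intervals == merged.intervals
        shuffled = RegionSet(tuple(reversed(intervals))).merge()
        assert shuffled.intervals == merged.intervals


class TestOverlaps:
    def test_touches_expanded_edge(self):
        rs = RegionSet.from_tuples([("chr1", 110, 120)])
        assert rs.overlaps(GenomicInterval("chr1", 100, 101), margin=10)

    def test_gap_of_one_remains(self):
        rs = RegionSet.from_tuples([("chr1", 112, 120)])
        assert not rs.overlaps(GenomicInterval("chr1", 100, 101), margin=10)

    def test_negative_margin_rejected(self):
        rs = RegionSet.from_tuples([("chr1", 0, 10)])
        with pytest.raises(ValidationError):
            rs.overlaps(GenomicInterval("chr1", 0, 1), margin=-1)

    def test_random_battery_against_per_base_oracle(self):
        rng = np.random.default_rng(3)
        size = 10_000
        intervals = []
        for _ in range(30):
            start = int(rng.integers(0, size - 500))
            intervals.append(GenomicInterval("chr1", start, start + int(rng.integers(1, 400))))
        rs = RegionSet(intervals)
        for margin in (0, 3, 25):
            covered = np.zeros(size + 1000, dtype=bool)
            for iv in intervals:
                covered[max(0, iv.start - margin) : iv.end + margin] = True
            for _ in range(300):
                qs = int(rng.integers(0, size))
                qe = qs + int(rng.integers(1, 50))
                expected = bool(covered[qs:qe].any())
                assert rs.overlaps(GenomicInterval("chr1", qs, qe), margin=margin) == expected

    def test_contains_span_requires_single_interval_containment(self):
        rs = RegionSet.from_tuples([("chr1", 100, 200), ("chr1", 300, 400)])
        assert rs.contains_span("chr1", 110, 190)
        assert rs.contains_span("chr1", 95, 205, margin=10)
        assert not rs.contains_span("chr1", 150, 350)  # straddles the gap
        assert not rs.contains_span("chr1", 80, 190)


class TestSetAlgebra:
    def test_complement_and_subtract_partition_the_genome(self):
        sizes = {"chr1": 1000}
        rs = RegionSet.from_tuples([("chr1", 100, 200), ("chr1", 500, 700)])
        comp = rs.complement(sizes)
        assert comp.total_bp == 1000 - rs.total_bp
        assert rs.subtract(rs).total_bp == 0
        whole = RegionSet.from_tuples([("chr1", 0, 1000)])
        assert whole.subtract(rs).total_bp == comp.total_bp


class TestGeneAnnotation:
    def test_two_transcript_span_is_maximal(self, tmp_path):
        gtf = (
            'chr1\tsrc\tgene\t1001\t2500\t.\t+\t.\tgene_id "G1"; gene_name "A";\n'
            'chr1\tsrc\ttranscript\t1001\t2000\t.\t+\t.\tgene_id "G1"; gene_name "A"; transcript_id "T1";\n'
            'chr1\tsrc\texon\t1001\t2000\t.\t+\t.\tgene_id "G1"; gene_name "A"; transcript_id "T1";\n'
            'chr1\tsrc\ttranscript\t1501\t2500\t.\t+\t.\tgene_id "G1"; gene_name "A"; transcript_id "T2";\n'
            'chr1\tsrc\texon\t1501\t2500\t.\t+\t.\tgene_id "G1"; gene_name "A"; transcript_id "T2";\n'
        )
        p = tmp_path / "toy.gtf"
        p.write_text(gtf)
        models, missing = read_gene_annotation(p)
        assert not missing
        (g,) = models
        assert (g.span.start, g.span.end) == (1000, 2500)
        assert g.tss == 1001

    def test_minus_strand_tss_is_highest_coordinate(self, tmp_path):
        gtf = (
            'chr1\tsrc\tgene\t1001\t2000\t.\t-\t.\tgene_id "G1"; gene_name "A";\n'
            'chr1\tsrc\ttranscript\t1001\t2000\t.\t-\t.\tgene_id "G1"; transcript_id "T1";\n'
            'chr1\tsrc\texon\t1001\t2000\t.\t-\t.\tgene_id "G1"; transcript_id "T1";\n'
        )
        p = tmp_path / "toy.gtf"
        p.write_text(gtf)
        models, _ = read_gene_annotation(p)
        assert models[0].tss == 2000

    def test_missing_genes_reported_not_raised(self, tmp_path, gene_fixture):
        _, gtf_text, _ = gene_fixture
        p = tmp_path / "genes.gtf"
        p.write_text(gtf_text)
        models, missing = read_gene_annotation(p, ["GENE1", "NOT_A_GENE"])
        assert [m.symbol for m in models] == ["GENE1"]
        assert missing == ["NOT_A_GENE"]

    def test_fixture_round_trip_matches_manifest(self, tmp_path, gene_fixture):
        genes, gtf_text, manifest = gene_fixture
        p = tmp_path / "genes.gtf"
        p.write_text(gtf_text)
        models, missing = read_gene_annotation(p)
        assert not missing
        by_symbol = {m.symbol: m for m in models}
        for symbol, info in manifest["genes"].items():
            m = by_symbol[symbol]
            assert [m.span.start, m.span.end] == info["span"]
            assert m.strand == info["strand"]
            assert m.tss == info["tss"]
            assert [len(t.exons) for t in m.transcripts] == info["exons_per_transcript"]
            for tx in m.transcripts:
                cds_bp = RegionSet(tx.cds)
                exon_bp = RegionSet(tx.exons)
                # CDS is contained in the exons
                assert cds_bp.subtract(exon_bp).total_bp == 0
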