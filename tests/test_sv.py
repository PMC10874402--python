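"""SV post-filter: elimination rules, pathogenic categories, idempotence."""

import pytest

from taslrs import simulate as sim
from taslrs.errors import ValidationError
from taslrs.regions import GenomicInterval, RegionSet
from taslrs.sv import (
    DELETION,
    DUPLICATION,
    INSERTION,
    INVERSION,
    PATH_DELETION_CDS,
    PATH_NONE,
    REASON_IN_REPEAT,
    REASON_NONPRIMARY,
    REASON_OFF_TARGET,
    SINGLE_BREAKEND,
    TRANSLOCATION,
    SvBreakend,
    SvRecord,
    classify_pathogenic_sv,
    eliminate_false_positives,
    read_sv_tsv,
    run_sv_pipeline,
    write_sv_classifications,
)

TARGETS = RegionSet.from_tuples([("chr1", 1_000, 50_000)])
REPEATS = RegionSet.from_tuples([("chr1", 10_000, 10_060)])
PRIMARY = {"chr1", "chr2"}


def _del(pos1, pos2, chrom="chr1", sv_id="d"):
    return SvRecord(sv_id, DELETION, SvBreakend(chrom, pos1), SvBreakend(chrom, pos2))


class TestRecordInvariants:
    def test_single_breakend_has_no_partner(self):
        with pytest.raises(ValidationError):
            SvRecord("x", SINGLE_BREAKEND, SvBreakend("chr1", 5), SvBreakend("chr1", 9))

    def test_translocation_requires_two_chromosomes(self):
        with pytest.raises(ValidationError):
            SvRecord("x", TRANSLOCATION, SvBreakend("chr1", 5), SvBreakend("chr1", 9))

    def test_deletion_requires_one_chromosome(self):
        with pytest.raises(ValidationError):
            SvRecord("x", DELETION, SvBreakend("chr1", 5), SvBreakend("chr2", 9))


class TestEliminationRules:
    def test_deletion_contained_in_padded_repeat_dropped(self):
        # both breakends inside the repeat interval +- 10 bp, breakend in target
        sv = _del(9_995, 10_065)  # 0-based 9994 and 10064: inside [9990, 10070)
        (cls,) = eliminate_false_positives([sv], TARGETS, REPEATS, PRIMARY)
        assert not cls.kept_after_fp_filter
        assert cls.fp_reasons == (REASON_IN_REPEAT,)

    def test_large_deletion_crossing_repeat_is_kept(self):
        sv = _del(9_000, 12_000)
        (cls,) = eliminate_false_positives([sv], TARGETS, REPEATS, PRIMARY)
        assert cls.kept_after_fp_filter

    def test_nonprimary_contig_dropped(self):
        sv = SvRecord("t", TRANSLOCATION, SvBreakend("chrUn_decoy", 100),
                      SvBreakend("chr1", 2_000))
        (cls,) = eliminate_false_positives([sv], TARGETS, REPEATS, PRIMARY)
        assert not cls.kept_after_fp_filter
        assert REASON_NONPRIMARY in cls.fp_reasons

    def test_no_breakend_in_target_dropped(self):
        sv = _del(60_000, 61_000)
        (cls,) = eliminate_false_positives([sv], TARGETS, REPEATS, PRIMARY)
        assert cls.fp_reasons == (REASON_OFF_TARGET,)

    def test_inversion_in_target_with_no_rule_fired_kept(self):
        sv = SvRecord("i", INVERSION, SvBreakend("chr1", 2_000), SvBreakend("chr1", 30_000))
        (cls,) = eliminate_false_positives([sv], TARGETS, REPEATS, PRIMARY)
        assert cls.kept_after_fp_filter and cls.fp_reasons == ()

    def test_insertion_point_margin_semantics(self):
        # repeat [10000,10060) padded by 10: insertion points within it drop
        inside = SvRecord("i1", INSERTION, SvBreakend("chr1", 9_991),
                          SvBreakend("chr1", 9_991))
        outside = SvRecord("i2", INSERTION, SvBreakend("chr1", 9_989),
                           SvBreakend("chr1", 9_989))
        res = eliminate_false_positives([inside, outside], TARGETS, REPEATS, PRIMARY)
        assert not res[0].kept_after_fp_filter
        assert res[1].kept_after_fp_filter

    def test_filter_is_idempotent(self):
        svs = [
            _del(9_995, 10_065, sv_id="a"),
            _del(9_000, 12_000, sv_id="b"),
            SvRecord("c", SINGLE_BREAKEND, SvBreakend("chr1", 5_000)),
        ]
        first = eliminate_false_positives(svs, TARGETS, REPEATS, PRIMARY)
        survivors = [c.record for c in first if c.kept_after_fp_filter]
        second = eliminate_false_positives(survivors, TARGETS, REPEATS, PRIMARY)
        assert all(c.kept_after_fp_filter for c in second)
        assert [c.record.sv_id for c in second] == [c.record.sv_id for c in first
                                                    if c.kept_after_fp_filter]


class TestPathogenicClassification:
    def test_deletion_over_last_cds_exons_of_neighbor_gene(self, genes):
        # a deletion running from one gene's intron through its neighbor,
        # covering CDS exons on the way, is pathogenic
        gene = genes[0]
        cds = sorted(gene.cds_region().intervals, key=lambda c: c.start)
        sv = _del(cds[-1].start - 50, cds[-1].end + 5_000, chrom=cds[-1].chrom)
        targets = RegionSet([gene.span.expand(10_000)])
        (cls,) = eliminate_false_positives([sv], targets, RegionSet(), {cds[-1].chrom})
        cls = classify_pathogenic_sv(cls, genes)
        assert cls.pathogenic and cls.pathogenic_reason == PATH_DELETION_CDS

    def test_intergenic_inversion_not_pathogenic(self, genes, target_design):
        gene = genes[0]
        pos = gene.span.end + 2_000  # inside margin, outside every span
        sv = SvRecord("i", INVERSION, SvBreakend(gene.span.chrom, pos),
                      SvBreakend(gene.span.chrom, pos + 500))
        (cls,) = eliminate_false_positives([sv], target_design.regions, RegionSet(),
                                           set(target_design.chrom_sizes))
        cls = classify_pathogenic_sv(cls, genes)
        assert not cls.pathogenic and cls.pathogenic_reason == PATH_NONE

    def test_duplication_confined_to_utr_not_pathogenic(self, genes, target_design):
        gene = genes[0]
        utr = sorted(gene.transcripts[0].utrs, key=lambda u: u.start)[0]
        sv = SvRecord("u", DUPLICATION, SvBreakend(utr.chrom, utr.start + 2),
                      SvBreakend(utr.chrom, utr.end))
        (cls,) = eliminate_false_positives([sv], target_design.regions, RegionSet(),
                                           set(target_design.chrom_sizes))
        cls = classify_pathogenic_sv(cls, genes)
        assert not cls.pathogenic

    def test_classification_requires_kept_record(self):
        sv = _del(60_000, 61_000)
        (cls,) = eliminate_false_positives([sv], TARGETS, REPEATS, PRIMARY)
        with pytest.raises(ValidationError):
            classify_pathogenic_sv(cls, [])


class TestManifestBattery:
    def test_fixture_callset_matches_manifest(self, genes, target_design, genome):
        fx = sim.make_sv_callset(1, genes, target_design.regions, genome.sizes)
        classified = run_sv_pipeline(
            fx.records, target_design.regions, fx.simple_repeats,
            set(genome.sizes), genes,
        )
        by_id = {c.record.sv_id: c for c in classified}
        for row in fx.manifest.itertuples(index=False):
            cls = by_id[row.sv_id]
            assert cls.kept_after_fp_filter == row.expect_kept, row.sv_id
            assert cls.pathogenic == row.expect_pathogenic, row.sv_id
            assert cls.pathogenic_reason == row.expect_reason, row.sv_id
            expected_reasons = () if row.expect_fp_reasons == "." else \
                tuple(row.expect_fp_reasons.split(","))
            assert cls.fp_reasons == expected_reasons, row.sv_id
        # pathogenic implies kept; exactly one reason per pathogenic call
        for cls in classified:
            if cls.pathogenic:
                assert cls.kept_after_fp_filter
                assert cls.pathogenic_reason != PATH_NONE

    def test_tsv_round_trip(self, tmp_path, genes, target_design, genome):
        fx = sim.make_sv_callset(1, genes, target_design.regions, genome.sizes)
        import pandas as pd
        rows = []
        for sv in fx.records:
            rows.append({
                "sv_id": sv.sv_id, "sv_type": sv.sv_type,
                "chrom1": sv.bp1.chrom, "pos1": sv.bp1.pos, "dir1": sv.bp1.orientation,
                "chrom2": sv.bp2.chrom if sv.bp2 else ".",
                "pos2": sv.bp2.pos if sv.bp2 else ".",
                "dir2": sv.bp2.orientation if sv.bp2 else ".",
                "inserted_seq": sv.inserted_seq or "",
            })
        p = tmp_path / "svs.tsv"
        pd.DataFrame(rows).to_csv(p, sep="\t", index=False)
        again = read_sv_tsv(p)
        assert [(s.sv_id, s.sv_type, s.bp1, s.bp2) for s in again] == \
            [(s.sv_id, s.sv_type, s.bp1, s.bp2) for s in fx.records]
        out = tmp_path / "cls.tsv"
        classified = run_sv_pipeline(again, target_design.regions, fx.simple_repeats,
                                     set(genome.sizes), genes)
        write_sv_classifications(classified, out)
        assert out.exists() and len(out.read_text().splitlines()) == len(again) + 1
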