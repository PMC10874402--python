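"""Structural-variant post-filtering and putative-pathogenic classification.

Works on the output of a long-read SV caller (breakpoint pairs or single
breakends, with inserted sequence where applicable).  Two stages:

1. False-positive elimination — drop a record when (a) any breakend sits on
   a non-primary contig (unplaced/decoy), (b) no breakend falls inside the
   sequencing target regions, or (c) a deletion/insertion/duplication is
   fully contained in one simple-repeat interval padded by 10 bp.
   "Contained" means both breakends (the single insertion point for
   insertions) fall inside one padded repeat interval; mere overlap with a
   repeat does not discard a record, so large deletions that merely cross a
   repeat survive.

2. Putative-pathogenic extraction over the target gene models — deletions
   hitting coding sequence; duplications with a breakend inside a gene
   (excluding UTRs) whose span covers at least one complete CDS interval;
   inversions/translocations with a breakend inside a gene excluding UTRs;
   and single breakends landing within a target gene span.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .errors import ParseError, ValidationError
from .regions import GeneModel, GenomicInterval, RegionSet

DELETION = "deletion"
INSERTION = "insertion"
DUPLICATION = "duplication"
INVERSION = "inversion"
TRANSLOCATION = "translocation"
SINGLE_BREAKEND = "single_breakend"
SV_TYPES = {DELETION, INSERTION, DUPLICATION, INVERSION, TRANSLOCATION, SINGLE_BREAKEND}

REPEAT_MARGIN = 10  # bp padding on simple-repeat intervals for rule (c)

REASON_NONPRIMARY = "nonprimary_contig"
REASON_OFF_TARGET = "no_breakend_in_target"
REASON_IN_REPEAT = "contained_in_simple_repeat"

PATH_DELETION_CDS = "deletion_hits_cds"
PATH_DUPLICATION_CDS = "duplication_alters_cds"
PATH_DISRUPTS_GENE = "disrupts_gene_body"
PATH_SINGLE_BND = "single_breakend_in_gene"
PATH_NONE = "none"


@dataclass(frozen=True)
class SvBreakend:
    chrom: str
    pos: int  # 1-based
    orientation: str = "+"

    def __post_init__(self):
        if self.pos < 1:
            raise ValidationError(f"breakend position must be >= 1, got {self.pos}")


@dataclass(frozen=True)
class SvRecord:
    sv_id: str
    sv_type: str
    bp1: SvBreakend
    bp2: SvBreakend | None = None
    inserted_seq: str | None = None

    def __post_init__(self):
        if self.sv_type not in SV_TYPES:
            raise ValidationError(f"unknown SV type {self.sv_type!r}")
        if self.sv_type == SINGLE_BREAKEND:
            if self.bp2 is not None:
                raise ValidationError("single breakend records carry no second breakpoint")
        elif self.bp2 is None:
            raise ValidationError(f"{self.sv_type} requires two breakends")
        elif self.sv_type in (DELETION, INSERTION, DUPLICATION, INVERSION):
            if self.bp1.chrom != self.bp2.chrom:
                raise ValidationError(f"{self.sv_type} breakends must share a chromosome")
        elif self.sv_type == TRANSLOCATION and self.bp1.chrom == self.bp2.chrom:
            raise ValidationError("translocation breakends must be on different chromosomes")

    @property
    def span(self) -> GenomicInterval | None:
        """Affected reference interval for intrachromosomal events."""
        if self.bp2 is None or self.bp1.chrom != self.bp2.chrom:
            return None
        lo, hi = sorted((self.bp1.pos, self.bp2.pos))
        return GenomicInterval(self.bp1.chrom, lo - 1, max(hi, lo + 1))

    @property
    def breakends(self) -> tuple[SvBreakend, ...]:
        return (self.bp1,) if self.bp2 is None else (self.bp1, self.bp2)


@dataclass
class SvClassification:
    record: SvRecord
    kept_after_fp_filter: bool
    fp_reasons: tuple[str, ...] = ()
    pathogenic: bool = False
    pathogenic_reason: str = PATH_NONE


def eliminate_false_positives(
    svs: Iterable[SvRecord],
    targets: RegionSet,
    simple_repeats: RegionSet,
    primary_contigs: set[str],
    repeat_margin: int = REPEAT_MARGIN,
) -> list[SvClassification]:
    """Apply the three elimination rules; every record is returned with its
    kept/dropped status and the reasons that fired."""
    out = []
    for sv in svs:
        reasons = []
        if any(be.chrom not in primary_contigs for be in sv.breakends):
            reasons.append(REASON_NONPRIMARY)
        if not any(
            targets.contains_point(be.chrom, be.pos - 1) for be in sv.breakends
        ):
            reasons.append(REASON_OFF_TARGET)
        if sv.sv_type in (DELETION, INSERTION, DUPLICATION):
            if sv.sv_type == INSERTION or sv.bp2 is None:
                pos0 = sv.bp1.pos - 1
                contained = simple_repeats.contains_point(
                    sv.bp1.chrom, pos0, margin=repeat_margin
                )
            else:
                span = sv.span
                contained = simple_repeats.contains_span(
                    span.chrom, span.start, span.end, margin=repeat_margin
                )
            if contained:
                reasons.append(REASON_IN_REPEAT)
        out.append(
            SvClassification(
                record=sv,
                kept_after_fp_filter=not reasons,
                fp_reasons=tuple(reasons),
            )
        )
    return out


def classify_pathogenic_sv(
    cls: SvClassification,
    genes: Sequence[GeneModel],
    single_bnd_exclude_utr: bool = False,
) -> SvClassification:
    """Assign the putative-pathogenic category to a kept record."""
    if not cls.kept_after_fp_filter:
        raise ValidationError("pathogenic classification requires a record kept by the FP filter")
    sv = cls.record
    reason = PATH_NONE

    def breakend_in(be: SvBreakend, region: RegionSet) -> bool:
        return region.contains_point(be.chrom, be.pos - 1)

    if sv.sv_type == DELETION:
        span = sv.span
        for gene in genes:
            if gene.cds_region().overlaps(span):
                reason = PATH_DELETION_CDS
                break
    elif sv.sv_type == DUPLICATION:
        span = sv.span
        for gene in genes:
            non_utr = gene.non_utr_region()
            if not any(breakend_in(be, non_utr) for be in sv.breakends):
                continue
            covered = any(
                span.chrom == cds.chrom and span.start <= cds.start and cds.end <= span.end
                for cds in gene.cds_region().intervals
            )
            if covered:
                reason = PATH_DUPLICATION_CDS
                break
    elif sv.sv_type in (INVERSION, TRANSLOCATION):
        for gene in genes:
            if any(breakend_in(be, gene.non_utr_region()) for be in sv.breakends):
                reason = PATH_DISRUPTS_GENE
                break
    elif sv.sv_type == SINGLE_BREAKEND:
        for gene in genes:
            region = gene.non_utr_region() if single_bnd_exclude_utr else RegionSet([gene.span])
            if breakend_in(sv.bp1, region):
                reason = PATH_SINGLE_BND
                break

    cls.pathogenic = reason != PATH_NONE
    cls.pathogenic_reason = reason
    return cls


def run_sv_pipeline(
    svs: Iterable[SvRecord],
    targets: RegionSet,
    simple_repeats: RegionSet,
    primary_contigs: set[str],
    genes: Sequence[GeneModel],
    repeat_margin: int = REPEAT_MARGIN,
) -> list[SvClassification]:
    """FP elimination followed by pathogenic classification of survivors."""
    classified = eliminate_false_positives(
        svs, targets, simple_repeats, primary_contigs, repeat_margin
    )
    for cls in classified:
        if cls.kept_after_fp_filter:
            classify_pathogenic_sv(cls, genes)
    return classified


# ---------------------------------------------------------------------------
# TSV I/O (the shape of a long-read SV caller's result table)

SV_TSV_COLUMNS = [
    "sv_id", "sv_type", "chrom1", "pos1", "dir1", "chrom2", "pos2", "dir2",
    "inserted_seq",
]


def read_sv_tsv(path) -> list[SvRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in SV_TSV_COLUMNS[:2] if c not in df.columns]
    if missing:
        raise ParseError(f"SV table missing columns {missing}", path)
    out = []
    for i, row in df.iterrows():
        bp2 = None
        if row.get("chrom2", "") not in ("", "."):
            bp2 = SvBreakend(row["chrom2"], int(row["pos2"]), row.get("dir2", "+") or "+")
        out.append(
            SvRecord(
                sv_id=row["sv_id"],
                sv_type=row["sv_type"],
                bp1=SvBreakend(row["chrom1"], int(row["pos1"]), row.get("dir1", "+") or "+"),
                bp2=bp2,
                inserted_seq=row.get("inserted_seq") or None,
            )
        )
    return out


def write_sv_classifications(classified: Sequence[SvClassification], path) -> None:
    rows = []
    for cls in classified:
        sv = cls.record
        rows.append(
            {
                "sv_id": sv.sv_id,
                "sv_type": sv.sv_type,
                "chrom1": sv.bp1.chrom,
                "pos1": sv.bp1.pos,
                "chrom2": sv.bp2.chrom if sv.bp2 else ".",
                "pos2": sv.bp2.pos if sv.bp2 else ".",
                "kept": cls.kept_after_fp_filter,
                "fp_reasons": ",".join(cls.fp_reasons) or ".",
                "pathogenic": cls.pathogenic,
                "pathogenic_reason": cls.pathogenic_reason,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
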