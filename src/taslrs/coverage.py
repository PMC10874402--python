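"""Adaptive-sampling QC: on/off-target depth, enrichment ratio, and N50.

Adaptive sampling ejects molecules that do not match the target list, so a
run yields deep coverage with long reads on target and shallow coverage
with short (rejected) reads elsewhere.  The summary statistics here mirror
a standard run-QC figure: mean per-base depth over targets and over the
rest of the genome, their ratio (enrichment), and per-class read N50.

Depth counts each primary alignment's reference footprint once; secondary
and supplementary alignments are excluded to avoid double-counting split
reads.  Unaligned reads contribute to neither depth but remain in read
counts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .errors import ValidationError
from .regions import GenomicInterval, RegionSet

ON_TARGET = "on_target"
OFF_TARGET = "off_target"


@dataclass(frozen=True)
class ReadAlignmentSummary:
    """One primary alignment: reference span plus the full read length."""

    read_id: str
    chrom: str
    aln_start: int
    aln_end: int
    read_length: int
    primary: bool = True

    def __post_init__(self):
        if not self.aln_start < self.aln_end:
            raise ValidationError(
                f"alignment {self.read_id}: require aln_start < aln_end"
            )

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.aln_start, self.aln_end)


@dataclass
class CoverageSummary:
    on_target_depth: float
    off_target_depth: float
    enrichment: float
    on_target_n50: int
    off_target_n50: int
    n_reads_on: int
    n_reads_off: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def classify_read(aln: ReadAlignmentSummary, targets: RegionSet) -> str:
    """on_target iff the alignment span overlaps the targets by >= 1 bp."""
    return ON_TARGET if targets.overlaps(aln.span) else OFF_TARGET


def mean_depth(alns: Iterable[ReadAlignmentSummary], regions: RegionSet) -> float:
    """Mean per-base depth over ``regions``: sum of overlapped bp / region bp."""
    total = regions.total_bp
    if total == 0:
        raise ValidationError("mean depth undefined over an empty region set")
    covered = sum(regions.overlap_bp(a.span) for a in alns)
    return covered / total


def n50(lengths: Sequence[int]) -> int:
    """Largest L such that reads of length >= L hold >= half of all bases."""
    if not lengths:
        raise ValidationError("N50 undefined for an empty length list")
    ordered = sorted(lengths, reverse=True)
    half = sum(ordered) / 2
    acc = 0
    for length in ordered:
        acc += length
        if acc >= half:
            return length
    return ordered[-1]  # unreachable


def summarize_sample(
    alns: Sequence[ReadAlignmentSummary],
    targets: RegionSet,
    chrom_sizes: dict[str, int],
    use_aligned_length: bool = False,
) -> CoverageSummary:
    """Full QC summary for one sample.

    Off-target is the genome complement of the targets over ``chrom_sizes``.
    N50 uses the full read length by default; set ``use_aligned_length`` to
    compute it over reference footprints instead.
    """
    off_regions = targets.complement(chrom_sizes)
    primaries = [a for a in alns if a.primary]
    on = [a for a in primaries if classify_read(a, targets) == ON_TARGET]
    off = [a for a in primaries if classify_read(a, targets) == OFF_TARGET]
    depth_on = mean_depth(on, targets) if len(targets) else 0.0
    depth_off = mean_depth(off, off_regions) if off_regions.total_bp else 0.0
    if depth_off > 0:
        enrichment = depth_on / depth_off
    else:
        warnings.warn("no off-target coverage; enrichment reported as +inf")
        enrichment = math.inf

    def length_of(a: ReadAlignmentSummary) -> int:
        return (a.aln_end - a.aln_start) if use_aligned_length else a.read_length

    return CoverageSummary(
        on_target_depth=depth_on,
        off_target_depth=depth_off,
        enrichment=enrichment,
        on_target_n50=n50([length_of(a) for a in on]) if on else 0,
        off_target_n50=n50([length_of(a) for a in off]) if off else 0,
        n_reads_on=len(on),
        n_reads_off=len(off),
    )


# ---------------------------------------------------------------------------
# I/O


def read_alignment_tsv(path) -> list[ReadAlignmentSummary]:
    """Read the 5-column alignment summary table (read_id, chrom, start, end,
    read_length); an optional sixth column flags primary alignments."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["read_id", "chrom", "start", "end", "read_length", "primary"],
    )
    df["primary"] = df["primary"].fillna(True).astype(bool)
    return [
        ReadAlignmentSummary(
            str(r.read_id), str(r.chrom), int(r.start), int(r.end),
            int(r.read_length), bool(r.primary),
        )
        for r in df.itertuples(index=False)
    ]


def read_alignment_bam(path) -> list[ReadAlignmentSummary]:
    """Summarize primary alignments from a BAM/SAM file."""
    import pysam

    out = []
    with pysam.AlignmentFile(str(path)) as bam:
        for rec in bam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            out.append(
                ReadAlignmentSummary(
                    rec.query_name,
                    rec.reference_name,
                    rec.reference_start,
                    rec.reference_end,
                    rec.infer_read_length() or rec.query_length,
                )
            )
    return out
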