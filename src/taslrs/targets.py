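"""Adaptive-sampling target BED construction.

Targets are built from the maximal span of each requested gene over all of
its transcripts, padded symmetrically by a margin (default 10 kbp, the value
used for the 147-gene hereditary-cancer panel), clipped at chromosome
bounds, unioned with any manual extension regions (e.g. an extra promoter
exon missing from the annotation release), and merged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .errors import ValidationError
from .regions import GeneModel, GenomicInterval, RegionSet

DEFAULT_MARGIN = 10_000


@dataclass
class TargetDesign:
    genes: tuple[GeneModel, ...]
    margin: int
    extra: RegionSet
    regions: RegionSet
    chrom_sizes: dict[str, int]

    @property
    def total_bp(self) -> int:
        return self.regions.total_bp


def build_target_regions(
    genes: Sequence[GeneModel],
    margin: int = DEFAULT_MARGIN,
    extra: RegionSet | None = None,
    chrom_sizes: dict[str, int] | None = None,
) -> TargetDesign:
    """Build the target region set from gene models.

    regions = merge( union of gene spans each padded by ``margin`` and
    clipped to [0, chrom length) ) union ``extra``.
    """
    if margin < 0:
        raise ValidationError("margin must be >= 0")
    extra = extra or RegionSet(label="extra")
    sizes = chrom_sizes or {}
    expanded = []
    for gene in genes:
        if chrom_sizes is not None and gene.span.chrom not in sizes:
            raise ValidationError(
                f"gene {gene.symbol}: chromosome {gene.span.chrom!r} absent "
                "from the chromosome-sizes table"
            )
        expanded.append(gene.span.expand(margin, sizes.get(gene.span.chrom)))
    regions = RegionSet(tuple(expanded) + tuple(extra.intervals), label="targets").merge()
    return TargetDesign(
        genes=tuple(genes),
        margin=margin,
        extra=extra,
        regions=regions,
        chrom_sizes=sizes,
    )


def design_report(td: TargetDesign) -> pd.DataFrame:
    """Per-gene review table: span, padded span, and merged-region id.

    Manual extension intervals are appended as extra rows tagged "extra".
    """
    merged = list(td.regions.intervals)

    def region_id(iv: GenomicInterval) -> int | None:
        for i, reg in enumerate(merged):
            if reg.overlaps(iv):
                return i
        return None

    rows = []
    for gene in td.genes:
        padded = gene.span.expand(td.margin, td.chrom_sizes.get(gene.span.chrom))
        rows.append(
            {
                "gene": gene.symbol,
                "chrom": gene.span.chrom,
                "span_start": gene.span.start,
                "span_end": gene.span.end,
                "span_bp": gene.span.length,
                "expanded_bp": padded.length,
                "region_id": region_id(padded),
                "kind": "gene",
            }
        )
    for iv in td.extra.intervals:
        rows.append(
            {
                "gene": "extra",
                "chrom": iv.chrom,
                "span_start": iv.start,
                "span_end": iv.end,
                "span_bp": iv.length,
                "expanded_bp": iv.length,
                "region_id": region_id(iv),
                "kind": "extra",
            }
        )
    return pd.DataFrame(rows)
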