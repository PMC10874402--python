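"""Coordinate engine: genomic intervals, region sets, and gene models.

All internal coordinates are 0-based half-open; 1-based inclusive values
(VCF positions, GTF features, coordinates quoted in text) are converted at
the I/O boundary only, via :meth:`GenomicInterval.from_one_based` /
:meth:`GenomicInterval.to_one_based`.  Chromosome names are compared by
exact string match ("chr6" is not "6"); callers that need aliasing supply a
rename map up front.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from .errors import ParseError, ValidationError

STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not self.chrom:
            raise ValidationError("interval chromosome name must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @classmethod
    def from_one_based(cls, chrom: str, start: int, end: int, strand: str = ".") -> "GenomicInterval":
        """Build from 1-based inclusive coordinates as printed in text/VCF/GTF."""
        return cls(chrom, start - 1, end, strand)

    def to_one_based(self) -> tuple[str, int, int]:
        """Return (chrom, start, end) in 1-based inclusive convention."""
        return self.chrom, self.start + 1, self.end

    def expand(self, margin: int, chrom_size: int | None = None) -> "GenomicInterval":
        """Symmetrically pad by ``margin`` bp, clipping at 0 and ``chrom_size``."""
        if margin < 0:
            raise ValidationError("margin must be >= 0")
        start = max(0, self.start - margin)
        end = self.end + margin
        if chrom_size is not None:
            end = min(end, chrom_size)
        return GenomicInterval(self.chrom, start, end, self.strand)

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_point(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


class RegionSet:
    """A queryable collection of intervals (targets, repeat masks, promoters...).

    ``intervals`` preserves the records as supplied; overlap queries run
    against a lazily built normalized index (per-chromosome sorted,
    merged).  ``merge()`` returns the normalized set itself.
    """

    def __init__(self, intervals: Iterable[GenomicInterval] = (), label: str | None = None):
        self.intervals: tuple[GenomicInterval, ...] = tuple(intervals)
        self.label = label
        self._index: dict[str, tuple[list[int], list[int]]] | None = None

    # -- construction -------------------------------------------------
    @classmethod
    def from_tuples(cls, tuples: Iterable[tuple], label: str | None = None) -> "RegionSet":
        return cls((GenomicInterval(*t) for t in tuples), label=label)

    # -- normalization ------------------------------------------------
    def _build_index(self) -> dict[str, tuple[list[int], list[int]]]:
        if self._index is None:
            per_chrom: dict[str, list[tuple[int, int]]] = {}
            for iv in self.intervals:
                per_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
            index = {}
            for chrom, ivs in per_chrom.items():
                ivs.sort()
                starts: list[int] = []
                ends: list[int] = []
                for s, e in ivs:
                    if ends and s <= ends[-1]:  # overlap or abutment
                        ends[-1] = max(ends[-1], e)
                    else:
                        starts.append(s)
                        ends.append(e)
                index[chrom] = (starts, ends)
            self._index = index
        return self._index

    def merge(self) -> "RegionSet":
        """Minimal sorted non-overlapping cover of the input (idempotent)."""
        index = self._build_index()
        merged = [
            GenomicInterval(chrom, s, e)
            for chrom in sorted(index)
            for s, e in zip(*index[chrom])
        ]
        out = RegionSet(merged, label=self.label)
        out._index = index
        return out

    @property
    def total_bp(self) -> int:
        """Total bp covered (union; equals sum of lengths once normalized)."""
        return sum(
            e - s
            for starts, ends in self._build_index().values()
            for s, e in zip(starts, ends)
        )

    # -- queries ------------------------------------------------------
    def overlaps(self, iv: GenomicInterval, margin: int = 0) -> bool:
        """True iff ``iv`` intersects any interval after padding each by ``margin``."""
        if margin < 0:
            raise ValidationError("margin must be >= 0")
        index = self._build_index()
        if iv.chrom not in index:
            return False
        starts, ends = index[iv.chrom]
        # first interval with end + margin > iv.start
        i = bisect.bisect_right(ends, iv.start - margin)
        return i < len(starts) and starts[i] - margin < iv.end

    def contains_point(self, chrom: str, pos: int, margin: int = 0) -> bool:
        if margin < 0:
            raise ValidationError("margin must be >= 0")
        index = self._build_index()
        if chrom not in index:
            return False
        starts, ends = index[chrom]
        i = bisect.bisect_right(ends, pos - margin)
        return i < len(starts) and starts[i] - margin <= pos

    def contains_span(self, chrom: str, start: int, end: int, margin: int = 0) -> bool:
        """True iff [start, end) lies inside ONE margin-padded interval."""
        index = self._build_index()
        if chrom not in index:
            return False
        starts, ends = index[chrom]
        i = bisect.bisect_right(starts, start + margin) - 1
        return i >= 0 and starts[i] - margin <= start and end <= ends[i] + margin

    def overlap_bp(self, iv: GenomicInterval) -> int:
        """Number of bases of ``iv`` covered by this set."""
        index = self._build_index()
        if iv.chrom not in index:
            return 0
        starts, ends = index[iv.chrom]
        i = bisect.bisect_right(ends, iv.start)
        bp = 0
        while i < len(starts) and starts[i] < iv.end:
            bp += min(ends[i], iv.end) - max(starts[i], iv.start)
            i += 1
        return bp

    # -- set algebra --------------------------------------------------
    def union(self, other: "RegionSet") -> "RegionSet":
        return RegionSet(self.intervals + other.intervals, label=self.label).merge()

    def expand(self, margin: int, chrom_sizes: dict[str, int] | None = None) -> "RegionSet":
        sizes = chrom_sizes or {}
        return RegionSet(
            (iv.expand(margin, sizes.get(iv.chrom)) for iv in self.intervals),
            label=self.label,
        ).merge()

    def complement(self, chrom_sizes: dict[str, int]) -> "RegionSet":
        """Genome minus this set, over the supplied chromosome sizes."""
        index = self._build_index()
        out = []
        for chrom in sorted(chrom_sizes):
            size = chrom_sizes[chrom]
            prev = 0
            for s, e in zip(*index.get(chrom, ([], []))):
                s, e = max(0, s), min(e, size)
                if s > prev:
                    out.append(GenomicInterval(chrom, prev, s))
                prev = max(prev, e)
            if prev < size:
                out.append(GenomicInterval(chrom, prev, size))
        return RegionSet(out, label=self.label)

    def subtract(self, other: "RegionSet") -> "RegionSet":
        """Bases of this set not covered by ``other`` (normalized output)."""
        oindex = other._build_index()
        out = []
        for iv in self.merge().intervals:
            cur = iv.start
            starts, ends = oindex.get(iv.chrom, ([], []))
            i = bisect.bisect_right(ends, iv.start)
            while i < len(starts) and starts[i] < iv.end:
                if starts[i] > cur:
                    out.append(GenomicInterval(iv.chrom, cur, starts[i]))
                cur = max(cur, ends[i])
                i += 1
            if cur < iv.end:
                out.append(GenomicInterval(iv.chrom, cur, iv.end))
        return RegionSet(out, label=self.label)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __repr__(self) -> str:
        return f"RegionSet({len(self.intervals)} intervals, {self.total_bp} bp, label={self.label!r})"


# ---------------------------------------------------------------------------
# BED I/O


def read_bed(path, label: str | None = None) -> RegionSet:
    """Read a 3+ column BED file into a RegionSet.

    BED is natively 0-based half-open, so coordinates are carried through
    unchanged.  Strand is taken from column 6 when present, else unstranded.
    Malformed lines raise :class:`ParseError` naming the line number;
    zero-length records (start >= end) are rejected.
    """
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError("expected >= 3 tab-separated columns", path, lineno)
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"non-integer coordinate: {exc}", path, lineno) from exc
            strand = fields[5] if len(fields) >= 6 and fields[5] in ("+", "-") else "."
            if start >= end or start < 0:
                raise ParseError(
                    f"rejected record {chrom}:{start}-{end}: require 0 <= start < end",
                    path,
                    lineno,
                )
            intervals.append(GenomicInterval(chrom, start, end, strand))
    return RegionSet(intervals, label=label)


def write_bed(rs: RegionSet, path) -> None:
    with open(path, "w") as fh:
        for iv in rs.intervals:
            if iv.strand == ".":
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t0\t{iv.strand}\n")


def read_chrom_sizes(path) -> dict[str, int]:
    """Read a two-column chrom<TAB>length table."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError("expected chrom<TAB>length", path, lineno)
            sizes[fields[0]] = int(fields[1])
    return sizes


# ---------------------------------------------------------------------------
# Gene models


@dataclass(frozen=True)
class TranscriptModel:
    tx_id: str
    span: GenomicInterval
    exons: tuple[GenomicInterval, ...]
    cds: tuple[GenomicInterval, ...] = ()
    utrs: tuple[GenomicInterval, ...] = ()

    @property
    def tss(self) -> int:
        """1-based transcription start position (5' end of the transcript)."""
        if self.span.strand == "-":
            return self.span.end
        return self.span.start + 1


@dataclass(frozen=True)
class GeneModel:
    """A gene as the maximal extent over its transcripts."""

    gene_id: str
    symbol: str
    strand: str
    span: GenomicInterval
    transcripts: tuple[TranscriptModel, ...] = ()

    @property
    def tss(self) -> int:
        """1-based TSS of the outermost (span-defining) transcript."""
        return self.span.end if self.strand == "-" else self.span.start + 1

    def cds_region(self) -> RegionSet:
        return RegionSet(
            (iv for tx in self.transcripts for iv in tx.cds), label="cds"
        ).merge()

    def utr_region(self) -> RegionSet:
        return RegionSet(
            (iv for tx in self.transcripts for iv in tx.utrs), label="utr"
        ).merge()

    def non_utr_region(self) -> RegionSet:
        """Gene span with UTR intervals excised."""
        return RegionSet([self.span]).subtract(self.utr_region())


def gene_spans(genes: Sequence[GeneModel], label: str = "gene_spans") -> RegionSet:
    return RegionSet((g.span for g in genes), label=label)


def read_gene_annotation(
    path, genes: Sequence[str] | None = None
) -> tuple[list[GeneModel], list[str]]:
    """Read gene models from a GENCODE-dialect GTF (or GFF3) file.

    Returns (models, missing): when ``genes`` is given, models are restricted
    to that list, matched on gene symbol (gene_name) first, then gene_id;
    names that match nothing are returned in ``missing`` rather than raising.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )

    def attr(feature, *keys):
        for key in keys:
            if key in feature.attributes:
                return feature.attributes[key][0]
        return None

    models: list[GeneModel] = []
    by_symbol: dict[str, GeneModel] = {}
    by_id: dict[str, GeneModel] = {}
    for gene in db.features_of_type("gene"):
        gene_id = attr(gene, "gene_id", "ID") or gene.id
        symbol = attr(gene, "gene_name", "Name") or gene_id
        strand = gene.strand if gene.strand in ("+", "-") else "."
        transcripts = []
        for tx in db.children(gene, featuretype=("transcript", "mRNA")):
            tx_id = attr(tx, "transcript_id", "ID") or tx.id
            exons = tuple(
                GenomicInterval(f.seqid, f.start - 1, f.end, strand)
                for f in db.children(tx, featuretype="exon", order_by="start")
            )
            cds = tuple(
                GenomicInterval(f.seqid, f.start - 1, f.end, strand)
                for f in db.children(tx, featuretype="CDS", order_by="start")
            )
            utrs = tuple(
                GenomicInterval(f.seqid, f.start - 1, f.end, strand)
                for f in db.children(
                    tx, featuretype=("UTR", "five_prime_UTR", "three_prime_UTR"),
                    order_by="start",
                )
            )
            span = GenomicInterval(tx.seqid, tx.start - 1, tx.end, strand)
            transcripts.append(TranscriptModel(tx_id, span, exons, cds, utrs))
        if transcripts:
            start = min(t.span.start for t in transcripts)
            end = max(t.span.end for t in transcripts)
        else:
            start, end = gene.start - 1, gene.end
        model = GeneModel(
            gene_id=gene_id,
            symbol=symbol,
            strand=strand,
            span=GenomicInterval(gene.seqid, start, end, strand),
            transcripts=tuple(transcripts),
        )
        models.append(model)
        by_symbol.setdefault(symbol, model)
        by_id.setdefault(gene_id, model)

    if genes is None:
        return models, []
    selected, missing = [], []
    for name in genes:
        model = by_symbol.get(name) or by_id.get(name)
        if model is None:
            missing.append(name)
        else:
            selected.append(model)
    return selected, missing
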