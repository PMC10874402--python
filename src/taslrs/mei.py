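"""Mobile-element-insertion characterization.

Given an insertion call (inserted sequence plus reference flanks), this
module reconstructs the anatomy of a retrotransposition event the way a
manual review would: target-site duplication (TSD) from the flanks,
3'-terminal poly-A tail, segmentation of the body against a repeat
consensus library (SVA subfamilies, L1, Alu...), tracing of the source
locus in a reference genome, identification of a 3' transduction (unique
genomic sequence downstream of the source element carried along during
retrotransposition, diagnostic of the source locus) including its AATAAA
polyadenylation signal, and detection of the 5' (CCCTCT)n hexamer head
whose loss marks a 5'-truncated, no-longer-mobile element.

Coordinate conventions: segment intervals are half-open offsets into the
TSD-trimmed inserted sequence; source/transduction loci are genome
intervals.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from . import align
from .errors import ValidationError
from .regions import GenomicInterval, RegionSet
from .sv import SvBreakend

MIN_INSERTION_LEN = 50

LABEL_TRANSDUCTION = "transduction"
LABEL_POLYA = "polyA"
LABEL_UNCLASSIFIED = "unclassified"

POLYA_SIGNAL = "AATAAA"
HEXAMER = "CCCTCT"
HEXAMER_WINDOW = 100


@dataclass(frozen=True)
class InsertionCall:
    """An insertion event: site, inserted sequence, and reference flanks."""

    site: SvBreakend
    inserted_seq: str
    left_flank: str
    right_flank: str

    def __post_init__(self):
        if len(self.inserted_seq) < MIN_INSERTION_LEN:
            raise ValidationError(
                f"inserted sequence of {len(self.inserted_seq)} bp is below the "
                f"{MIN_INSERTION_LEN} bp mobile-element scope"
            )


@dataclass(frozen=True)
class LibraryEntry:
    name: str
    family: str
    seq: str


class RepeatLibrary:
    """Named repeat consensus sequences with family labels."""

    def __init__(self, entries: Sequence[LibraryEntry]):
        names = [e.name for e in entries]
        if len(set(names)) != len(names):
            raise ValidationError("repeat library names must be unique")
        if any(not e.seq for e in entries):
            raise ValidationError("repeat library sequences must be non-empty")
        self.entries: dict[str, LibraryEntry] = {e.name: e for e in entries}

    @classmethod
    def from_fasta(cls, path) -> "RepeatLibrary":
        """Load consensus sequences; the first '#'-separated token of each
        header is the name, the second (if any) the family label."""
        entries = []
        name, family, chunks = None, None, []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line.startswith(">"):
                    if name is not None:
                        entries.append(LibraryEntry(name, family or name, "".join(chunks)))
                    head = line[1:].split()[0]
                    parts = head.split("#")
                    name = parts[0]
                    family = parts[1] if len(parts) > 1 else parts[0]
                    chunks = []
                else:
                    chunks.append(line.upper())
        if name is not None:
            entries.append(LibraryEntry(name, family or name, "".join(chunks)))
        return cls(entries)

    def __iter__(self):
        return iter(self.entries.values())


@dataclass(frozen=True)
class MeiSegment:
    start: int  # offsets into the TSD-trimmed inserted sequence
    end: int
    label: str  # family name, "transduction", "polyA", or "unclassified"
    source: tuple[str, int, int] | None = None  # consensus or genome interval
    identity: float | None = None

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class MeiAnnotation:
    segments: list[MeiSegment]
    tsd_seq: str | None
    tsd_len: int
    polya_len: int
    transduction_len: int
    polya_signal_found: bool
    source_locus: GenomicInterval | None
    hexamer_head_present: bool
    five_prime_truncated: bool
    strand: str = "+"

    def to_dict(self) -> dict:
        return {
            "segments": [
                {
                    "start": s.start, "end": s.end, "label": s.label,
                    "source": s.source, "identity": s.identity,
                }
                for s in self.segments
            ],
            "tsd_seq": self.tsd_seq,
            "tsd_len": self.tsd_len,
            "polya_len": self.polya_len,
            "transduction_len": self.transduction_len,
            "polya_signal_found": self.polya_signal_found,
            "source_locus": (
                None if self.source_locus is None
                else [self.source_locus.chrom, self.source_locus.start, self.source_locus.end]
            ),
            "hexamer_head_present": self.hexamer_head_present,
            "five_prime_truncated": self.five_prime_truncated,
            "strand": self.strand,
        }


# ---------------------------------------------------------------------------
# Primitives


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def detect_tsd(
    call: InsertionCall,
    max_tsd: int = 50,
    min_tsd: int = 5,
    max_mismatch: int = 1,
) -> str | None:
    """Longest target-site duplication consistent with the flanks.

    Callers differ in whether the duplicated bases ride along at the 3' end
    of the reported insertion (right flank begins with the TSD) or at its
    5' end (left flank ends with the TSD); both conventions are scanned and
    ties break toward the longer duplication.
    """
    if len(call.left_flank) < max_tsd or len(call.right_flank) < max_tsd:
        raise ValidationError(f"flanks must be at least max_tsd={max_tsd} bp long")
    left_ext = call.left_flank + call.inserted_seq
    right_ext = call.inserted_seq + call.right_flank
    for l in range(max_tsd, min_tsd - 1, -1):
        cand = call.right_flank[:l]
        if _hamming(left_ext[-l:], cand) <= max_mismatch:
            return cand
        cand = call.left_flank[-l:]
        if _hamming(right_ext[:l], cand) <= max_mismatch:
            return cand
    return None


def detect_polya(seq: str, min_len: int = 10, max_mismatch_frac: float = 0.1) -> int:
    """Length of the 3'-terminal poly-A tract.

    The tail is the longest 3'-terminal window whose non-A fraction stays
    at or below ``max_mismatch_frac`` and whose 5'-most base is an A (a
    window that opens on a mismatch is never the canonical tail).  Returns
    0 when the best window is shorter than ``min_len``.
    """
    best = 0
    non_a = 0
    n = len(seq)
    for i in range(1, n + 1):
        base = seq[n - i]
        if base != "A":
            non_a += 1
        elif non_a <= max_mismatch_frac * i:
            best = i
    return best if best >= min_len else 0


def detect_hexamer_head(seq: str, min_repeats: int = 2) -> bool:
    """True iff >= min_repeats tandem (CCCTCT) copies start within the first
    100 bp of the element's 5' segment."""
    window = seq[: HEXAMER_WINDOW + len(HEXAMER) * min_repeats - 1]
    m = re.search(f"(?:{HEXAMER}){{{min_repeats},}}", window)
    return m is not None and m.start() < HEXAMER_WINDOW


def segment_against_library(
    seq: str,
    lib: RepeatLibrary,
    min_identity: float = 80.0,
    min_seg: int = 100,
    k: int = align.DEFAULT_K,
) -> list[MeiSegment]:
    """Tile ``seq`` with repeat-library alignments.

    Candidate local alignments (exact k-mer diagonal runs) are selected
    greedily by length, requiring no query overlap with already-selected
    segments, length >= ``min_seg`` and identity >= ``min_identity``.
    Gaps between selected segments are emitted as unclassified segments so
    the output always tiles [0, len(seq)).
    """
    candidates: list[tuple[align.Hsp, LibraryEntry]] = []
    for entry in lib:
        for hsp in align.chain_hsps(seq, entry.seq, k=k, max_gap=2 * k):
            if hsp.length >= min_seg:
                candidates.append((hsp, entry))
    candidates.sort(key=lambda c: c[0].length, reverse=True)
    selected: list[MeiSegment] = []
    for hsp, entry in candidates:
        # trim against already-selected segments (chance extensions and the
        # shared SVA hexamer head produce small overlaps); keep the larger
        # remaining side when a selected segment splits the candidate
        lo, hi, tlo, thi = hsp.qstart, hsp.qend, hsp.tstart, hsp.tend
        for s in sorted(selected, key=lambda s: s.start):
            if s.end <= lo or hi <= s.start:
                continue
            left = s.start - lo
            right = hi - s.end
            if right >= left:
                shift = s.end - lo
                lo, tlo = s.end, tlo + shift
            else:
                trim = hi - s.start
                hi, thi = s.start, thi - trim
            if lo >= hi:
                break
        if hi - lo < min_seg:
            continue
        ident = align.identity_pct(seq[lo:hi], entry.seq[tlo:thi])
        if ident < min_identity:
            continue
        selected.append(
            MeiSegment(
                start=lo,
                end=hi,
                label=entry.name,
                source=(entry.name, tlo, thi),
                identity=ident,
            )
        )
    selected.sort(key=lambda s: s.start)
    # tile with unclassified gaps
    tiled: list[MeiSegment] = []
    cursor = 0
    for seg in selected:
        if seg.start > cursor:
            tiled.append(MeiSegment(cursor, seg.start, LABEL_UNCLASSIFIED))
        tiled.append(seg)
        cursor = seg.end
    if cursor < len(seq):
        tiled.append(MeiSegment(cursor, len(seq), LABEL_UNCLASSIFIED))
    return tiled


def trace_source_and_transduction(
    seq: str,
    reference: Mapping[str, str],
    repeat_mask: RegionSet,
    polya_len: int = 0,
    k: int = align.DEFAULT_K,
    min_score: int = 50,
    max_contig_gap: int = 1000,
) -> tuple[GenomicInterval | None, GenomicInterval | None, bool]:
    """Locate the source locus of ``seq`` (poly-A already removed unless
    ``polya_len`` is given here) and its 3' transduction.

    The body is aligned to every reference sequence; the best co-linear
    chain defines the source locus.  The transduction is the 3'-terminal
    aligned stretch falling outside the repeat mask while remaining
    genomically contiguous (within ``max_contig_gap``) with the masked
    element.  Returns (source_locus, transduction_interval, signal_found).
    """
    body = seq[: len(seq) - polya_len] if polya_len else seq
    if len(body) < k:
        return None, None, False
    best: tuple[int, str, list[align.Hsp]] | None = None
    for chrom, ref_seq in reference.items():
        hsps = align.chain_hsps(body, ref_seq, k=k, max_gap=2 * k)
        chain = align.best_chain(hsps)
        score = sum(h.length for h in chain)
        if chain and (best is None or score > best[0]):
            best = (score, chrom, chain)
    if best is None or best[0] < min_score:
        return None, None, False
    _, chrom, chain = best
    tmin = min(h.tstart for h in chain)
    tmax = max(h.tend for h in chain)
    locus = GenomicInterval(chrom, tmin, tmax)

    # 3'-terminal aligned genomic position: the HSP containing the query end
    tail_hsp = max(chain, key=lambda h: h.qend)
    unmasked = RegionSet([locus]).subtract(repeat_mask)
    transduction = None
    q_tail_pos = tail_hsp.tend  # genomic coordinate aligned to the query 3' end
    for piece in unmasked.intervals:
        if piece.start <= q_tail_pos <= piece.end or piece.contains_point(chrom, q_tail_pos - 1):
            masked_part = RegionSet([locus]).subtract(unmasked)
            gap = min(
                (abs(piece.start - m.end) for m in masked_part.intervals),
                default=0,
            ) if masked_part.intervals else 0
            if gap <= max_contig_gap:
                transduction = piece
            break
    signal = False
    if transduction is not None:
        td_len = transduction.length
        signal = POLYA_SIGNAL in body[len(body) - td_len :]
    return locus, transduction, signal


# ---------------------------------------------------------------------------
# Orchestration


def annotate_insertion(
    call: InsertionCall,
    lib: RepeatLibrary,
    reference: Mapping[str, str] | None = None,
    repeat_mask: RegionSet | None = None,
    min_identity: float = 80.0,
    min_seg: int = 100,
    max_tsd: int = 50,
    min_tsd: int = 5,
) -> MeiAnnotation:
    """Full anatomy of one insertion: TSD -> strand -> poly-A -> library
    segmentation -> source locus & transduction -> 5' hexamer head."""
    seq = call.inserted_seq.upper()
    left = call.left_flank.upper()
    right = call.right_flank.upper()

    norm_call = InsertionCall(call.site, seq, left, right)
    tsd_seq = detect_tsd(norm_call, max_tsd=max_tsd, min_tsd=min_tsd)
    tsd_len = len(tsd_seq) if tsd_seq else 0

    # trim the duplicated bases off the inserted sequence if the caller
    # carried them there (either end), so segmentation sees the element only
    core = seq
    if tsd_seq:
        if _hamming(core[-tsd_len:], tsd_seq) <= 1:
            core = core[:-tsd_len]
        elif _hamming(core[:tsd_len], tsd_seq) <= 1:
            core = core[tsd_len:]

    # strand normalization after trimming: a minus-strand event carries the
    # poly-A as a 5' poly-T head, which the TSD would otherwise hide
    strand = "+"
    if detect_polya(align.revcomp(core)) > detect_polya(core):
        core = align.revcomp(core)
        strand = "-"

    polya_len = detect_polya(core)
    body = core[: len(core) - polya_len]

    segments = segment_against_library(body, lib, min_identity=min_identity, min_seg=min_seg)

    source_locus, transduction_iv, signal = (None, None, False)
    if reference is not None:
        source_locus, transduction_iv, signal = trace_source_and_transduction(
            body, reference, repeat_mask or RegionSet(), polya_len=0
        )
    transduction_len = transduction_iv.length if transduction_iv is not None else 0

    # relabel the 3'-terminal unclassified gap matching the transduction
    if transduction_len:
        relabeled = []
        for seg in segments:
            if (
                seg.label == LABEL_UNCLASSIFIED
                and seg.end == len(body)
                and seg.length >= transduction_len - 5
            ):
                # a repeat segment may overrun the true junction by a few
                # chance base matches, so clamp the query-side segment to
                # the gap; the reported length stays genome-derived
                td_query = min(transduction_len, seg.length)
                if seg.length > td_query:
                    relabeled.append(
                        MeiSegment(seg.start, seg.end - td_query, LABEL_UNCLASSIFIED)
                    )
                relabeled.append(
                    MeiSegment(
                        len(body) - td_query,
                        len(body),
                        LABEL_TRANSDUCTION,
                        source=(
                            transduction_iv.chrom,
                            transduction_iv.start,
                            transduction_iv.end,
                        ),
                    )
                )
            else:
                relabeled.append(seg)
        segments = relabeled

    if polya_len:
        segments.append(MeiSegment(len(body), len(core), LABEL_POLYA))

    repeat_segs = [s for s in segments if s.label not in
                   (LABEL_UNCLASSIFIED, LABEL_TRANSDUCTION, LABEL_POLYA)]
    if repeat_segs:
        head = detect_hexamer_head(body[repeat_segs[0].start :])
    else:
        head = detect_hexamer_head(body)

    ann = MeiAnnotation(
        segments=segments,
        tsd_seq=tsd_seq,
        tsd_len=tsd_len,
        polya_len=polya_len,
        transduction_len=transduction_len,
        polya_signal_found=signal,
        source_locus=source_locus,
        hexamer_head_present=head,
        five_prime_truncated=not head,
        strand=strand,
    )
    covered = sum(s.length for s in ann.segments)
    if covered != len(core):
        raise AssertionError(
            f"segment tiling covers {covered} bp but the trimmed insertion is {len(core)} bp"
        )
    return ann
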