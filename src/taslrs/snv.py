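"""Germline SNV/indel prioritization.

Candidate pathogenic variants are selected by a chain of pure predicates —
caller quality strictly above 10, position inside the maximal gene spans but
outside simple-repeat and segmental-duplication masks, and population
allele frequency below 1% in every configured source — followed by a
three-way pathogenicity classification:

* ``known_pathogenic`` — ClinVar significance Pathogenic / Likely
  pathogenic (including the slash-combined form), case-insensitive;
* ``splicing`` — an essential GT-AG splice-site consequence
  (splice_acceptor_variant / splice_donor_variant) or a SpliceAI delta
  score (max of DS_AG, DS_AL, DS_DG, DS_DL) of 0.50 or greater;
* ``lof`` — LOFTEE high-confidence loss of function.

A variant may carry several labels; summaries report distinct variants by
set union (inclusion–exclusion over label multisets).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .errors import ValidationError
from .regions import RegionSet

LABEL_KNOWN = "known_pathogenic"
LABEL_LOF = "lof"
LABEL_SPLICING = "splicing"

ESSENTIAL_SPLICE_TERMS = {"splice_acceptor_variant", "splice_donor_variant"}
PATHOGENIC_CLNSIG = {
    "pathogenic",
    "likely pathogenic",
    "likely_pathogenic",
    "pathogenic/likely_pathogenic",
    "pathogenic/likely pathogenic",
}

DEFAULT_AF_THRESHOLD = 0.01
DEFAULT_QUALITY_THRESHOLD = 10.0
DEFAULT_SPLICEAI_THRESHOLD = 0.50


@dataclass(frozen=True)
class AnnotatedVariant:
    """An SNV/indel with the annotations the prioritizer consumes."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    quality: float | None = None
    af: Mapping[str, float] = field(default_factory=dict)
    clinvar_sig: str | None = None
    consequences: frozenset[str] = frozenset()
    spliceai_ds: tuple[float, float, float, float] | None = None
    loftee: str | None = None  # "HC" | "LC" | None
    tags: frozenset[str] = frozenset()  # informational (e.g. splicing DBs)

    def __post_init__(self):
        for source, freq in self.af.items():
            if not (0.0 <= freq <= 1.0):
                raise ValidationError(
                    f"{self.chrom}:{self.pos} allele frequency {source}={freq} outside [0,1]"
                )
        if self.spliceai_ds is not None:
            if len(self.spliceai_ds) != 4 or not all(
                0.0 <= d <= 1.0 for d in self.spliceai_ds
            ):
                raise ValidationError(
                    f"{self.chrom}:{self.pos} SpliceAI delta scores must be four values in [0,1]"
                )

    @property
    def max_spliceai(self) -> float | None:
        if self.spliceai_ds is None:
            return None
        return max(self.spliceai_ds)


@dataclass(frozen=True)
class PathogenicityCall:
    variant: AnnotatedVariant
    labels: frozenset[str]


def quality_filter(
    v: AnnotatedVariant,
    min_q: float = DEFAULT_QUALITY_THRESHOLD,
    keep_missing: bool = False,
) -> bool:
    """Keep iff quality > min_q (records at exactly min_q are removed)."""
    if v.quality is None:
        warnings.warn(f"{v.chrom}:{v.pos} has no quality value; "
                      + ("kept" if keep_missing else "dropped"))
        return keep_missing
    return v.quality > min_q


def in_analysis_region(
    v: AnnotatedVariant,
    gene_spans: RegionSet,
    simple_repeats: RegionSet,
    segdups: RegionSet,
) -> bool:
    """Inside the maximal gene spans and outside both repeat masks."""
    pos0 = v.pos - 1
    return (
        gene_spans.contains_point(v.chrom, pos0)
        and not simple_repeats.contains_point(v.chrom, pos0)
        and not segdups.contains_point(v.chrom, pos0)
    )


def is_common(
    v: AnnotatedVariant,
    threshold: float = DEFAULT_AF_THRESHOLD,
    require_all: bool = False,
) -> bool:
    """True iff a population frequency reaches ``threshold`` (inclusive).

    By default a variant is common when ANY source is at/above the
    threshold (OR over sources); ``require_all`` switches to AND.  A source
    with no entry counts as frequency 0.
    """
    freqs = list(v.af.values())
    if not freqs:
        return False
    hits = [f >= threshold for f in freqs]
    return all(hits) if require_all else any(hits)


def classify(
    v: AnnotatedVariant,
    spliceai_threshold: float = DEFAULT_SPLICEAI_THRESHOLD,
) -> PathogenicityCall:
    """Assign the pathogenicity labels (assumes upstream filters passed)."""
    labels = set()
    if v.clinvar_sig is not None and v.clinvar_sig.strip().lower() in PATHOGENIC_CLNSIG:
        labels.add(LABEL_KNOWN)
    if (v.consequences & ESSENTIAL_SPLICE_TERMS) or (
        v.max_spliceai is not None and v.max_spliceai >= spliceai_threshold
    ):
        labels.add(LABEL_SPLICING)
    if v.loftee == "HC":
        labels.add(LABEL_LOF)
    return PathogenicityCall(variant=v, labels=frozenset(labels))


def prioritize(
    variants: Iterable[AnnotatedVariant],
    gene_spans: RegionSet,
    simple_repeats: RegionSet,
    segdups: RegionSet,
    min_q: float = DEFAULT_QUALITY_THRESHOLD,
    af_threshold: float = DEFAULT_AF_THRESHOLD,
    spliceai_threshold: float = DEFAULT_SPLICEAI_THRESHOLD,
    keep_missing_quality: bool = False,
    af_require_all: bool = False,
) -> list[PathogenicityCall]:
    """Apply the full filter chain and return labeled survivors only."""
    calls = []
    for v in variants:
        if not quality_filter(v, min_q, keep_missing_quality):
            continue
        if not in_analysis_region(v, gene_spans, simple_repeats, segdups):
            continue
        if is_common(v, af_threshold, af_require_all):
            continue
        call = classify(v, spliceai_threshold)
        if call.labels:
            calls.append(call)
    return calls


def summarize(calls: Sequence[PathogenicityCall]) -> dict:
    """Per-label counts, multi-label count, and distinct-variant total."""
    per_label = {LABEL_KNOWN: 0, LABEL_LOF: 0, LABEL_SPLICING: 0}
    distinct = set()
    multi = 0
    for call in calls:
        key = (call.variant.chrom, call.variant.pos, call.variant.ref, call.variant.alt)
        for label in call.labels:
            per_label[label] = per_label.get(label, 0) + 1
        if len(call.labels) > 1:
            multi += 1
        if call.labels:
            distinct.add(key)
    return {
        "per_label": per_label,
        "multi_label": multi,
        "distinct_total": len(distinct),
    }


# ---------------------------------------------------------------------------
# VCF input

DEFAULT_INFO_KEYS = {
    "gnomad": "gnomAD_AF",
    "tommo": "TOMMO_AF",
    "clinvar": "CLNSIG",
    "loftee": "LoF",
    "consequence": "Consequence",
    "spliceai": ("SpliceAI_DS_AG", "SpliceAI_DS_AL", "SpliceAI_DS_DG", "SpliceAI_DS_DL"),
}


def read_annotated_vcf(path, info_keys: Mapping | None = None) -> list[AnnotatedVariant]:
    """Read annotated variants from a VCF with configurable INFO key mapping."""
    from cyvcf2 import VCF

    keys = dict(DEFAULT_INFO_KEYS)
    if info_keys:
        keys.update(info_keys)
    out = []
    for rec in VCF(str(path)):
        af = {}
        for source in ("gnomad", "tommo"):
            val = rec.INFO.get(keys[source])
            if val is not None:
                af[source] = float(val)
        ds_vals = [rec.INFO.get(k) for k in keys["spliceai"]]
        spliceai = (
            tuple(float(d) for d in ds_vals) if all(d is not None for d in ds_vals) else None
        )
        csq = rec.INFO.get(keys["consequence"])
        consequences = frozenset(str(csq).split("&")) if csq else frozenset()
        clnsig = rec.INFO.get(keys["clinvar"])
        out.append(
            AnnotatedVariant(
                chrom=rec.CHROM,
                pos=rec.POS,
                ref=rec.REF,
                alt=rec.ALT[0] if rec.ALT else ".",
                quality=rec.QUAL,
                af=af,
                clinvar_sig=str(clnsig) if clnsig is not None else None,
                consequences=consequences,
                spliceai_ds=spliceai,
                loftee=str(rec.INFO.get(keys["loftee"])) if rec.INFO.get(keys["loftee"]) else None,
            )
        )
    return out
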