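"""MAF-binned genotype concordance between a test and a truth call set.

Evaluates how well low-coverage imputed genotypes (e.g. from adaptive
sampling off-target reads) reproduce a high-confidence truth set, the way
imputation-accuracy tools report it: biallelic sites are matched on
(chrom, pos, ref, alt), the truth set is filtered on depth and genotype
confidence, sites are stratified by reference-panel minor allele
frequency, and per-bin genotype concordance (% identical alt-allele
dosages) and non-reference concordance are reported.  Dosages (0/1/2), not
phased genotypes, are compared: a phase switch is not a concordance error.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

DEFAULT_BINS = (0.000, 0.001, 0.002, 0.005, 0.010, 0.050, 0.100, 0.200, 0.500)
DEFAULT_MIN_DEPTH = 8
DEFAULT_MIN_GQ_PROB = 0.9999

SiteKey = tuple[str, int, str, str]


@dataclass(frozen=True)
class GenotypeRecord:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    gt: int  # alt-allele dosage 0/1/2
    maf: float
    truth_depth: int | None = None
    truth_gq_prob: float | None = None

    def __post_init__(self):
        if self.gt not in (0, 1, 2):
            raise ValidationError(f"genotype dosage must be 0/1/2, got {self.gt}")

    @property
    def key(self) -> SiteKey:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class ConcordanceReport:
    edges: tuple[float, ...]
    table: pd.DataFrame  # bin_low, bin_high, n_sites, concordance_pct, nonref_concordance_pct
    n_compared: int
    n_rejected_maf: int


def bin_by_maf(
    records: Sequence[GenotypeRecord],
    edges: Sequence[float] = DEFAULT_BINS,
) -> tuple[dict[int, list[GenotypeRecord]], int]:
    """Partition records into half-open MAF bins [e_i, e_{i+1}) with the last
    bin closed at the top.  Records with MAF outside [min_edge, max_edge]
    are rejected and counted, not raised."""
    edges = tuple(edges)
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValidationError("bin edges must be strictly increasing")
    bins: dict[int, list[GenotypeRecord]] = {i: [] for i in range(len(edges) - 1)}
    rejected = 0
    lo, hi = edges[0], edges[-1]
    for rec in records:
        if not (lo <= rec.maf <= hi):
            rejected += 1
            continue
        if rec.maf == hi:
            idx = len(edges) - 2
        else:
            idx = int(np.searchsorted(edges, rec.maf, side="right")) - 1
        bins[idx].append(rec)
    return bins, rejected


def concordance(
    truth: Sequence[GenotypeRecord],
    test: Sequence[GenotypeRecord],
    edges: Sequence[float] = DEFAULT_BINS,
    min_depth: int = DEFAULT_MIN_DEPTH,
    min_gq_prob: float = DEFAULT_MIN_GQ_PROB,
) -> ConcordanceReport:
    """Per-MAF-bin concordance of ``test`` against the filtered ``truth``.

    Truth records with depth below ``min_depth`` or confidence below
    ``min_gq_prob`` are excluded before comparison.  Bins with no
    comparable site report concordance as absent (NaN), not 0.
    """
    kept_truth = {
        r.key: r
        for r in truth
        if (r.truth_depth is None or r.truth_depth >= min_depth)
        and (r.truth_gq_prob is None or r.truth_gq_prob >= min_gq_prob)
    }
    paired = [(kept_truth[r.key], r) for r in test if r.key in kept_truth]
    binned, rejected = bin_by_maf([t for t, _ in paired], edges)
    test_by_key = {r.key: r for r in test}

    rows = []
    edges = tuple(edges)
    for i in range(len(edges) - 1):
        members = binned[i]
        n = len(members)
        if n == 0:
            rows.append(
                {"bin_low": edges[i], "bin_high": edges[i + 1], "n_sites": 0,
                 "concordance_pct": np.nan, "nonref_concordance_pct": np.nan}
            )
            continue
        match = 0
        nonref_total = 0
        nonref_match = 0
        for t in members:
            s = test_by_key[t.key]
            same = t.gt == s.gt
            match += same
            if t.gt != 0 or s.gt != 0:
                nonref_total += 1
                nonref_match += same
        rows.append(
            {
                "bin_low": edges[i],
                "bin_high": edges[i + 1],
                "n_sites": n,
                "concordance_pct": 100.0 * match / n,
                "nonref_concordance_pct": (
                    100.0 * nonref_match / nonref_total if nonref_total else np.nan
                ),
            }
        )
    table = pd.DataFrame(rows)
    return ConcordanceReport(
        edges=edges,
        table=table,
        n_compared=int(table["n_sites"].sum()),
        n_rejected_maf=rejected,
    )


# ---------------------------------------------------------------------------
# VCF input


def read_genotypes_vcf(
    path,
    maf_by_site: Mapping[SiteKey, float] | None = None,
    af_info_key: str = "AF",
) -> list[GenotypeRecord]:
    """Read biallelic genotype records for a single sample.

    MAF comes from ``maf_by_site`` when given (a reference-panel side
    table), else from the INFO ``AF`` field folded to min(AF, 1-AF).
    Unsplit multi-allelic records are rejected with a clear error: split
    them (e.g. `bcftools norm -m -any`) first.
    """
    from cyvcf2 import VCF

    out = []
    for rec in VCF(str(path)):
        if len(rec.ALT) != 1:
            raise ValidationError(
                f"{path}: multi-allelic record at {rec.CHROM}:{rec.POS}; "
                "split to biallelic records before concordance evaluation"
            )
        key = (rec.CHROM, rec.POS, rec.REF, rec.ALT[0])
        if maf_by_site is not None:
            if key not in maf_by_site:
                continue
            maf = maf_by_site[key]
        else:
            af = rec.INFO.get(af_info_key)
            if af is None:
                continue
            af = float(af)
            maf = min(af, 1.0 - af)
        gts = rec.genotypes[0]
        alleles = [g for g in gts[:-1] if g >= 0]
        if not alleles:
            continue
        dosage = int(sum(1 for g in alleles if g > 0))
        try:
            depth = rec.format("DP")
        except KeyError:
            depth = None
        try:
            gq_prob = rec.format("GP")
        except KeyError:
            gq_prob = None
        out.append(
            GenotypeRecord(
                chrom=rec.CHROM,
                pos=rec.POS,
                ref=rec.REF,
                alt=rec.ALT[0],
                gt=dosage,
                maf=maf,
                truth_depth=int(depth[0][0]) if depth is not None else None,
                truth_gq_prob=float(np.max(gq_prob[0])) if gq_prob is not None else None,
            )
        )
    return out


def read_af_table(path) -> dict[SiteKey, float]:
    """Side table chrom<TAB>pos<TAB>ref<TAB>alt<TAB>af -> MAF map."""
    df = pd.read_csv(path, sep="\t")
    out = {}
    for row in df.itertuples(index=False):
        af = float(row.af)
        out[(row.chrom, int(row.pos), row.ref, row.alt)] = min(af, 1.0 - af)
    return out
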