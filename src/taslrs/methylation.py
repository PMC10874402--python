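"""Allele-specific methylation aberration (epimutation) calling.

Haplotype-resolved per-CpG methylation counts from a target sample are
compared against a panel of control samples (default 10):

1. Site classes from the controls — a CpG is "normally unmethylated" when
   every control shows a methylation ratio in [0, 0.2] (with at least
   ``min_cov`` reads), "normally methylated" when every control is in
   [0.8, 1], otherwise "other".
2. Per-site calls — at a normally unmethylated site, a target haplotype
   with ratio strictly above 0.2 and a two-sided Fisher exact p-value of
   0.05 or below (target counts vs controls pooled over samples and
   haplotypes) is hypermethylated; the mirrored rule (ratio <= 0.8) gives
   hypomethylation at normally methylated sites.
3. Gene flagging — aberrant CpGs within the 2000 bp promoter window
   upstream of the TSS are collected per gene and haplotype; a gene is
   flagged when the mean of -log10(p) over those sites reaches 4.5, or
   when 10 or more such sites accumulate.

No site-level multiple-testing correction is applied; the gene-level
4.5 / 10 thresholds are the stringency mechanism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .errors import ValidationError
from .regions import GeneModel, GenomicInterval

NORMALLY_UNMETHYLATED = "normally_unmethylated"
NORMALLY_METHYLATED = "normally_methylated"
OTHER = "other"

HYPER = "hyper"
HYPO = "hypo"
NONE = "none"

DEFAULT_MIN_CONTROL_COV = 5
DEFAULT_ALPHA = 0.05
DEFAULT_LOW = 0.2
DEFAULT_HIGH = 0.8
DEFAULT_PROMOTER_WIDTH = 2000
DEFAULT_MEAN_THRESHOLD = 4.5
DEFAULT_COUNT_THRESHOLD = 10


@dataclass(frozen=True)
class CpgCounts:
    chrom: str
    pos: int  # 1-based position of the CpG cytosine
    haplotype: int | str  # 1, 2 or "unassigned"
    n_meth: int
    n_unmeth: int

    def __post_init__(self):
        if self.n_meth < 0 or self.n_unmeth < 0:
            raise ValidationError("methylation counts must be >= 0")

    @property
    def coverage(self) -> int:
        return self.n_meth + self.n_unmeth


@dataclass(frozen=True)
class SiteCall:
    chrom: str
    pos: int
    haplotype: int | str
    direction: str  # hyper | hypo | none
    p_value: float | None
    target_ratio: float | None
    site_class: str


@dataclass
class GeneMethylationReport:
    gene: GeneModel
    haplotype: int
    n_aberrant: int
    mean_neg_log10_p: float | None
    flagged: bool


def methylation_ratio(n_meth: int, n_unmeth: int) -> float | None:
    """#methylated / (#methylated + #unmethylated); None at zero coverage."""
    total = n_meth + n_unmeth
    if total == 0:
        return None
    return n_meth / total


def classify_site(
    control_counts: Sequence[tuple[int, int]],
    min_cov: int = DEFAULT_MIN_CONTROL_COV,
    low: float = DEFAULT_LOW,
    high: float = DEFAULT_HIGH,
) -> str:
    """Site class from per-control (n_meth, n_unmeth) pairs.

    "All controls" is strict: one control outside the band, or below the
    coverage floor, sends the site to "other".
    """
    if not control_counts:
        return OTHER
    ratios = []
    for n_meth, n_unmeth in control_counts:
        if n_meth + n_unmeth < min_cov:
            return OTHER
        ratios.append(n_meth / (n_meth + n_unmeth))
    if all(r <= low for r in ratios):
        return NORMALLY_UNMETHYLATED
    if all(r >= high for r in ratios):
        return NORMALLY_METHYLATED
    return OTHER


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Point-probability method: with margins fixed, sum the hypergeometric
    probabilities of every table whose probability does not exceed that of
    the observed table.  An all-zero table returns 1 by convention.
    """
    if min(a, b, c, d) < 0:
        raise ValidationError("Fisher table counts must be >= 0")
    n = a + b + c + d
    if n == 0:
        return 1.0
    row1 = a + b
    col1 = a + c
    if col1 in (0, n) or row1 in (0, n):
        return 1.0  # margins admit a single table
    lo = max(0, col1 - (c + d))
    hi = min(col1, row1)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, n, row1, col1)
    p_obs = pmf[support == a][0]
    # relative guard absorbs floating-point jitter on exact ties
    p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    return min(p, 1.0)


def call_site(
    target: CpgCounts,
    pooled_controls: tuple[int, int],
    site_class: str,
    alpha: float = DEFAULT_ALPHA,
    low: float = DEFAULT_LOW,
    high: float = DEFAULT_HIGH,
) -> SiteCall:
    """Hyper/hypo call for one target haplotype at one classified CpG.

    Hyper needs a normally unmethylated site, target ratio strictly above
    ``low`` and p <= alpha; hypo needs a normally methylated site, target
    ratio at or below ``high`` and p <= alpha.
    """
    ratio = methylation_ratio(target.n_meth, target.n_unmeth)
    if ratio is None or site_class == OTHER:
        return SiteCall(target.chrom, target.pos, target.haplotype, NONE,
                        None, ratio, site_class)
    p = fisher_two_sided(
        target.n_meth, target.n_unmeth, pooled_controls[0], pooled_controls[1]
    )
    direction = NONE
    if site_class == NORMALLY_UNMETHYLATED and ratio > low and p <= alpha:
        direction = HYPER
    elif site_class == NORMALLY_METHYLATED and ratio <= high and p <= alpha:
        direction = HYPO
    return SiteCall(target.chrom, target.pos, target.haplotype, direction,
                    p, ratio, site_class)


def promoter_window(g: GeneModel, width: int = DEFAULT_PROMOTER_WIDTH,
                    chrom_size: int | None = None) -> GenomicInterval:
    """The ``width`` bp immediately upstream of the gene's TSS (strand-aware,
    clipped at chromosome bounds)."""
    tss = g.tss  # 1-based
    if g.strand == "-":
        start, end = tss, tss + width
    else:
        start, end = tss - 1 - width, tss - 1
    start = max(0, start)
    if chrom_size is not None:
        end = min(end, chrom_size)
    if start >= end:
        # fully clipped away (TSS at the chromosome edge): empty 1 bp sentinel
        start, end = max(0, end - 1), max(1, end)
    return GenomicInterval(g.span.chrom, start, end, g.strand)


def score_genes(
    calls: Iterable[SiteCall],
    genes: Sequence[GeneModel],
    mean_threshold: float = DEFAULT_MEAN_THRESHOLD,
    count_threshold: int = DEFAULT_COUNT_THRESHOLD,
    promoter_width: int = DEFAULT_PROMOTER_WIDTH,
) -> list[GeneMethylationReport]:
    """Promoter-window aberration reports per gene x haplotype."""
    aberrant = [c for c in calls if c.direction in (HYPER, HYPO)]
    reports = []
    for gene in genes:
        window = promoter_window(gene, promoter_width)
        for hap in (1, 2):
            in_window = [
                c for c in aberrant
                if c.haplotype == hap and window.contains_point(c.chrom, c.pos - 1)
            ]
            n = len(in_window)
            if n == 0:
                reports.append(GeneMethylationReport(gene, hap, 0, None, False))
                continue
            mean_nlp = float(np.mean([-math.log10(max(c.p_value, 1e-300)) for c in in_window]))
            flagged = mean_nlp >= mean_threshold or n >= count_threshold
            reports.append(GeneMethylationReport(gene, hap, n, mean_nlp, flagged))
    return reports


# ---------------------------------------------------------------------------
# Table-level pipeline

METH_COLUMNS = ["chrom", "pos", "haplotype", "n_meth", "n_unmeth"]


def read_methylation_tsv(path) -> pd.DataFrame:
    """Per-CpG haplotype-resolved count table (chrom, pos, haplotype,
    n_meth, n_unmeth) — the shape of an haplotype-split meth-freq output."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in METH_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"methylation table {path} missing columns {missing}")
    return df


def run_epimutation(
    target: pd.DataFrame,
    controls: Sequence[pd.DataFrame],
    genes: Sequence[GeneModel],
    min_cov: int = DEFAULT_MIN_CONTROL_COV,
    alpha: float = DEFAULT_ALPHA,
    mean_threshold: float = DEFAULT_MEAN_THRESHOLD,
    count_threshold: int = DEFAULT_COUNT_THRESHOLD,
    promoter_width: int = DEFAULT_PROMOTER_WIDTH,
    include_unassigned: bool = False,
) -> tuple[list[SiteCall], list[GeneMethylationReport]]:
    """End-to-end epimutation screen from count tables.

    Controls are summarized per site by summing haplotypes within each
    sample (for site classes) and pooling across all samples (for the
    Fisher comparison).  Target haplotypes 1 and 2 are called separately;
    haplotype-unassigned target reads are excluded unless requested.
    """
    ctrl_per_sample = []
    for df in controls:
        g = df.groupby(["chrom", "pos"])[["n_meth", "n_unmeth"]].sum()
        ctrl_per_sample.append(g)
    pooled = (
        pd.concat(ctrl_per_sample).groupby(level=["chrom", "pos"]).sum()
        if ctrl_per_sample
        else pd.DataFrame(columns=["n_meth", "n_unmeth"])
    )

    site_class: dict[tuple[str, int], str] = {}
    for key in pooled.index:
        per_control = [
            (int(g.loc[key, "n_meth"]), int(g.loc[key, "n_unmeth"]))
            if key in g.index
            else (0, 0)
            for g in ctrl_per_sample
        ]
        site_class[key] = classify_site(per_control, min_cov=min_cov)

    calls = []
    haps = (1, 2) if not include_unassigned else (1, 2, "unassigned")
    tgt = target[target["haplotype"].isin(haps)]
    for row in tgt.itertuples(index=False):
        key = (row.chrom, int(row.pos))
        cls = site_class.get(key, OTHER)
        counts = CpgCounts(row.chrom, int(row.pos), row.haplotype,
                           int(row.n_meth), int(row.n_unmeth))
        if cls == OTHER:
            calls.append(SiteCall(counts.chrom, counts.pos, counts.haplotype, NONE,
                                  None, methylation_ratio(counts.n_meth, counts.n_unmeth), cls))
            continue
        pool = (int(pooled.loc[key, "n_meth"]), int(pooled.loc[key, "n_unmeth"]))
        calls.append(call_site(counts, pool, cls, alpha=alpha))
    reports = score_genes(
        calls, genes,
        mean_threshold=mean_threshold,
        count_threshold=count_threshold,
        promoter_width=promoter_width,
    )
    return calls, reports


def site_calls_frame(calls: Sequence[SiteCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": c.chrom, "pos": c.pos, "haplotype": c.haplotype,
                "direction": c.direction, "p_value": c.p_value,
                "target_ratio": c.target_ratio, "site_class": c.site_class,
            }
            for c in calls
        ]
    )


def gene_reports_frame(reports: Sequence[GeneMethylationReport]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": r.gene.symbol, "haplotype": r.haplotype,
                "n_aberrant": r.n_aberrant,
                "mean_neg_log10_p": r.mean_neg_log10_p, "flagged": r.flagged,
            }
            for r in reports
        ]
    )
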