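"""Deterministic synthetic fixtures with ground-truth manifests.

Every input the pipeline consumes can be emulated here: a random genome
with planted repeat loci, GENCODE-style gene annotation, a repeat consensus
library and planted retrotransposition events, haplotype-resolved CpG count
tables with one epimutated promoter, genotype call-set pairs with planted
per-bin discordance, SV callsets with one exemplar per filter rule and
pathogenic category, and read alignment summaries reproducing the on/off
target enrichment and N50 magnitudes of an adaptive-sampling run
(defaults: 10x enrichment, 9 kb / 0.6 kb N50, 10 methylation controls).

Each generator draws from its own labeled random substream of the master
seed, so adding a generator never perturbs the others, and regenerating
with the same seed is byte-identical.  Manifests record the planted ground
truth that downstream assertions compare against.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import methylation as meth
from .concordance import DEFAULT_BINS, GenotypeRecord
from .coverage import ReadAlignmentSummary
from .errors import ValidationError
from .mei import InsertionCall, LibraryEntry, RepeatLibrary
from .regions import GeneModel, GenomicInterval, RegionSet, TranscriptModel
from .sv import (
    DELETION, DUPLICATION, INSERTION, INVERSION, SINGLE_BREAKEND,
    TRANSLOCATION, SvBreakend, SvRecord,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_NONA = np.frombuffer(b"CGT", dtype=np.uint8)


def substream(seed: int, label: str) -> np.random.Generator:
    """Labeled child RNG of the master seed (stable across generators)."""
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(zlib.crc32(label.encode()),))
    )


def random_seq(rng: np.random.Generator, n: int, bases: np.ndarray = _BASES) -> str:
    return bases[rng.integers(0, len(bases), n)].tobytes().decode()


# ---------------------------------------------------------------------------
# Genome


@dataclass
class SyntheticGenome:
    seqs: dict[str, str]
    repeat_mask: RegionSet
    manifest: dict

    @property
    def sizes(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.seqs.items()}

    def overwrite(self, chrom: str, start: int, segment: str) -> None:
        seq = self.seqs[chrom]
        if start < 0 or start + len(segment) > len(seq):
            raise ValidationError("planted segment exceeds chromosome bounds")
        self.seqs[chrom] = seq[:start] + segment + seq[start + len(segment):]

    def fetch(self, chrom: str, start: int, end: int) -> str:
        return self.seqs[chrom][start:end]


def make_genome(
    seed: int,
    lengths: dict[str, int] | None = None,
    n_repeats_per_chrom: int = 4,
    repeat_len: int = 300,
) -> SyntheticGenome:
    """Uniform random genome with planted tandem-repeat loci.

    Planted repeats are tandem copies of a short random motif; their
    intervals form the simple-repeat mask.
    """
    lengths = lengths or {"chr1": 120_000, "chr2": 80_000}
    if any(n < 10_000 for n in lengths.values()):
        raise ValidationError("chromosome lengths must be >= 10 kb")
    rng = substream(seed, "genome")
    seqs = {}
    mask = []
    for chrom in sorted(lengths):
        n = lengths[chrom]
        seq = random_seq(rng, n)
        placed: list[tuple[int, int]] = []
        for _ in range(n_repeats_per_chrom):
            motif = random_seq(rng, int(rng.integers(2, 7)))
            copies = repeat_len // len(motif) + 1
            tract = (motif * copies)[:repeat_len]
            for _attempt in range(50):
                start = int(rng.integers(1000, n - repeat_len - 1000))
                if all(start + repeat_len + 200 < s or start > e + 200 for s, e in placed):
                    break
            else:
                continue
            seq = seq[:start] + tract + seq[start + repeat_len:]
            placed.append((start, start + repeat_len))
            mask.append(GenomicInterval(chrom, start, start + repeat_len))
        seqs[chrom] = seq
    return SyntheticGenome(
        seqs=seqs,
        repeat_mask=RegionSet(mask, label="simple_repeats").merge(),
        manifest={
            "seed": seed,
            "lengths": dict(lengths),
            "repeats": [[iv.chrom, iv.start, iv.end] for iv in mask],
        },
    )


# ---------------------------------------------------------------------------
# Gene annotation


def _place_interval(
    rng: np.random.Generator,
    genome: SyntheticGenome,
    length: int,
    avoid: RegionSet,
    margin: int = 500,
    chrom: str | None = None,
    max_tries: int = 200,
) -> GenomicInterval:
    chroms = [chrom] if chrom else sorted(genome.seqs)
    for _ in range(max_tries):
        c = chroms[int(rng.integers(0, len(chroms)))]
        size = genome.sizes[c]
        if size - length - 2 * margin <= 2500:
            continue
        start = int(rng.integers(2500, size - length - margin))
        iv = GenomicInterval(c, start, start + length)
        if not avoid.overlaps(iv, margin=margin):
            return iv
    raise ValidationError("could not place an interval; genome too crowded")


def make_gene_annotation(
    seed: int,
    genome: SyntheticGenome,
    n_genes: int = 12,
    min_span: int = 6_000,
    max_span: int = 18_000,
    max_exons: int = 8,
    avoid: RegionSet | None = None,
) -> tuple[list[GeneModel], str, dict]:
    """Random multi-exon genes on both strands; returns (models, GTF text,
    manifest).  Gene spans avoid the repeat mask and each other; promoter
    room (2.5 kb) is kept clear of chromosome edges."""
    rng = substream(seed, "genes")
    occupied = RegionSet(avoid.intervals if avoid else ()).union(genome.repeat_mask)
    genes: list[GeneModel] = []
    manifest: dict = {"seed": seed, "genes": {}}
    for i in range(n_genes):
        span_len = int(rng.integers(min_span, max_span + 1))
        iv = _place_interval(rng, genome, span_len, occupied, margin=3000)
        occupied = occupied.union(RegionSet([iv]))
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(2, max_exons + 1))
        # exon boundaries: first exon starts at span start, last ends at span end
        inner = np.sort(rng.choice(
            np.arange(iv.start + 200, iv.end - 200), size=2 * n_exons - 2, replace=False
        ))
        bounds = [iv.start, *[int(x) for x in inner], iv.end]
        exons = tuple(
            GenomicInterval(iv.chrom, bounds[2 * j], bounds[2 * j + 1], strand)
            for j in range(n_exons)
        )
        # strand-aware UTRs within the terminal exons
        utr_left = min(100, exons[0].length // 2) or 1
        utr_right = min(100, exons[-1].length // 2) or 1
        utrs = (
            GenomicInterval(iv.chrom, exons[0].start, exons[0].start + utr_left, strand),
            GenomicInterval(iv.chrom, exons[-1].end - utr_right, exons[-1].end, strand),
        )
        cds = []
        for j, ex in enumerate(exons):
            s, e = ex.start, ex.end
            if j == 0:
                s += utr_left
            if j == n_exons - 1:
                e -= utr_right
            if s < e:
                cds.append(GenomicInterval(iv.chrom, s, e, strand))
        gene_id = f"G{i:06d}"
        symbol = f"GENE{i + 1}"
        tx1 = TranscriptModel(f"{gene_id}.t1", GenomicInterval(iv.chrom, iv.start, iv.end, strand),
                              exons, tuple(cds), utrs)
        transcripts = [tx1]
        if n_exons >= 4 and rng.random() < 0.5:
            sub = exons[1:-1]
            tx2 = TranscriptModel(
                f"{gene_id}.t2",
                GenomicInterval(iv.chrom, sub[0].start, sub[-1].end, strand),
                sub,
            )
            transcripts.append(tx2)
        gene = GeneModel(gene_id, symbol, strand,
                         GenomicInterval(iv.chrom, iv.start, iv.end, strand),
                         tuple(transcripts))
        genes.append(gene)
        manifest["genes"][symbol] = {
            "gene_id": gene_id,
            "chrom": iv.chrom,
            "span": [iv.start, iv.end],
            "strand": strand,
            "tss": gene.tss,
            "exons_per_transcript": [len(t.exons) for t in transcripts],
        }
    return genes, genes_to_gtf(genes), manifest


def genes_to_gtf(genes: Sequence[GeneModel]) -> str:
    """GENCODE-dialect GTF text for the given gene models."""
    def line(chrom, feature, iv, strand, attrs):
        attr = " ".join(f'{k} "{v}";' for k, v in attrs)
        return f"{chrom}\ttaslrs\t{feature}\t{iv.start + 1}\t{iv.end}\t.\t{strand}\t.\t{attr}\n"

    out = []
    for g in genes:
        base = [("gene_id", g.gene_id), ("gene_name", g.symbol)]
        out.append(line(g.span.chrom, "gene", g.span, g.strand, base))
        for tx in g.transcripts:
            tattrs = base + [("transcript_id", tx.tx_id)]
            out.append(line(g.span.chrom, "transcript", tx.span, g.strand, tattrs))
            for ex in tx.exons:
                out.append(line(g.span.chrom, "exon", ex, g.strand, tattrs))
            for cds in tx.cds:
                out.append(line(g.span.chrom, "CDS", cds, g.strand, tattrs))
            for utr in tx.utrs:
                out.append(line(g.span.chrom, "UTR", utr, g.strand, tattrs))
    return "".join(out)


# ---------------------------------------------------------------------------
# Repeat library & mobile element events

SVA_FAMILIES = ("SVA_A", "SVA_B", "SVA_C", "SVA_D", "SVA_E", "SVA_F")


def make_repeat_library(seed: int, sva_len: int = 1400, l1_len: int = 3000,
                        alu_len: int = 300) -> RepeatLibrary:
    """Random per-family consensus sequences; SVA consensi open with the
    (CCCTCT)n hexamer head required for retrotransposition."""
    rng = substream(seed, "repeat_library")
    entries = []
    head = "CCCTCT" * 6
    for fam in SVA_FAMILIES:
        entries.append(LibraryEntry(fam, "SVA", head + random_seq(rng, sva_len - len(head))))
    entries.append(LibraryEntry("L1", "LINE1", random_seq(rng, l1_len)))
    entries.append(LibraryEntry("AluY", "Alu", random_seq(rng, alu_len)))
    return RepeatLibrary(entries)


def library_to_fasta(lib: RepeatLibrary, path) -> None:
    with open(path, "w") as fh:
        for entry in lib:
            fh.write(f">{entry.name}#{entry.family}\n")
            for i in range(0, len(entry.seq), 60):
                fh.write(entry.seq[i:i + 60] + "\n")


@dataclass
class MeiFixture:
    call: InsertionCall
    genome: SyntheticGenome
    lib: RepeatLibrary
    manifest: dict


def make_mei_event(
    seed: int,
    genome: SyntheticGenome,
    lib: RepeatLibrary,
    tsd_len: int = 14,
    polya_len: int = 24,
    transduction_len: int = 82,
    families: Sequence[tuple[str, int, int]] = (("SVA_F", 200, 1400), ("SVA_F", 0, 1200)),
    truncation: int = 150,
    flank: int = 100,
    avoid: RegionSet | None = None,
) -> MeiFixture:
    """Plant a retrotransposition source locus and build the insertion call.

    The source locus (element copies followed by a unique downstream tail
    carrying an AATAAA signal) is written into the genome and its element
    part added to the repeat mask.  The insertion is the 5'-truncated
    element plus the tail (3' transduction), a poly-A tract, and the
    duplicated target-site bases; flanks come from the reference around the
    insertion point.
    """
    if transduction_len < 12:
        raise ValidationError("transduction must be >= 12 bp to carry the AATAAA signal")
    if polya_len < 10 or tsd_len < 5 or tsd_len > 50:
        raise ValidationError("planted polyA/TSD lengths conflict with detector thresholds")
    rng = substream(seed, "mei")
    element_parts = []
    for name, s, e in families:
        if name not in lib.entries:
            raise ValidationError(f"family {name!r} not in repeat library")
        element_parts.append(lib.entries[name].seq[s:e])
    element = "".join(element_parts)
    if truncation >= len(element_parts[0]):
        raise ValidationError("truncation exceeds the first element segment")

    # unique downstream tail: AATAAA mid-tail.  The 3' end (the cleavage
    # site region) is kept non-A-rich so the poly-A tract added at
    # insertion has a crisp 5' boundary: the poly-A detector tolerates a
    # 10% non-A fraction, so the run of non-A bases must outgrow
    # (polya_len + 1) / 9 or the tail would absorb upstream A's.
    guard = polya_len // 6 + 3
    if transduction_len < guard + 12:
        raise ValidationError(
            "transduction too short for the AATAAA signal plus the "
            f"{guard} bp non-A cleavage guard"
        )
    tail = random_seq(rng, transduction_len)
    sig_at = (transduction_len - guard) // 2 - 3
    tail = tail[:sig_at] + "AATAAA" + tail[sig_at + 6:]
    tail = tail[:-guard] + random_seq(rng, guard, _NONA)

    avoid_all = RegionSet(
        tuple(avoid.intervals if avoid else ()) + tuple(genome.repeat_mask.intervals)
    )
    src = _place_interval(rng, genome, len(element) + transduction_len, avoid_all, margin=500)
    genome.overwrite(src.chrom, src.start, element + tail)
    element_iv = GenomicInterval(src.chrom, src.start, src.start + len(element))
    genome.repeat_mask = genome.repeat_mask.union(RegionSet([element_iv]))

    site_iv = _place_interval(
        rng, genome, tsd_len + 2 * flank,
        avoid_all.union(RegionSet([src])), margin=500,
    )
    site = site_iv.start + flank
    tsd_seq = genome.fetch(site_iv.chrom, site, site + tsd_len)
    inserted = element[truncation:] + tail + "A" * polya_len + tsd_seq
    call = InsertionCall(
        site=SvBreakend(site_iv.chrom, site + 1),
        inserted_seq=inserted,
        left_flank=genome.fetch(site_iv.chrom, site - flank, site),
        right_flank=genome.fetch(site_iv.chrom, site, site + flank),
    )
    # segment boundaries in TSD-trimmed insertion coordinates
    bounds = []
    cursor = 0
    for idx, part in enumerate(element_parts):
        length = len(part) - (truncation if idx == 0 else 0)
        bounds.append([cursor, cursor + length])
        cursor += length
    manifest = {
        "seed": seed,
        "tsd_len": tsd_len,
        "tsd_seq": tsd_seq,
        "polya_len": polya_len,
        "transduction_len": transduction_len,
        "families": [f[0] for f in families],
        "segment_bounds": bounds,
        "source_locus": [src.chrom, src.start + truncation,
                         src.start + len(element) + transduction_len],
        "element_locus": [element_iv.chrom, element_iv.start, element_iv.end],
        "truncation": truncation,
        # the hexamer head survives only when the insertion starts at the
        # very 5' end of an SVA consensus
        "hexamer_head_present": (
            truncation == 0
            and families[0][1] == 0
            and lib.entries[families[0][0]].family == "SVA"
        ),
        "site": [site_iv.chrom, site],
    }
    return MeiFixture(call=call, genome=genome, lib=lib, manifest=manifest)


def make_mei_fixture(seed: int, **event_kwargs) -> MeiFixture:
    """Self-contained event: fresh small genome + library + planted event."""
    genome = make_genome(seed, lengths={"chrS": 40_000}, n_repeats_per_chrom=2)
    lib = make_repeat_library(seed)
    return make_mei_event(seed, genome, lib, **event_kwargs)


# ---------------------------------------------------------------------------
# Methylation dataset


@dataclass
class MethylationFixture:
    target: pd.DataFrame
    controls: list[pd.DataFrame]
    genes: list[GeneModel]
    manifest: dict


def make_methylation_dataset(
    seed: int,
    genes: Sequence[GeneModel],
    genome: SyntheticGenome,
    n_controls: int = 10,
    coverage_per_hap: int = 10,
    promoter_background: float = 0.03,
    body_background: float = 0.85,
    epimutated_gene: str | None = None,
    epimutated_haplotype: int = 2,
    epimutation_ratio: float = 0.9,
    promoter_width: int = meth.DEFAULT_PROMOTER_WIDTH,
    max_body_cpgs: int = 30,
) -> MethylationFixture:
    """Haplotype-resolved CpG count tables for a target and a control panel.

    CpG positions are the genome's CG dinucleotides inside each gene's
    promoter window (unmethylated background) and gene body (methylated
    background, capped per gene).  In the target, the chosen gene's chosen
    haplotype has hypermethylated promoter CpGs.  Counts are binomial at
    the per-site ratio with fixed per-haplotype coverage.
    """
    rng = substream(seed, "methylation")
    sites: list[tuple[str, int, float]] = []  # (chrom, 1-based pos of C, background ratio)
    planted_sites = []
    for gene in genes:
        window = meth.promoter_window(gene, promoter_width,
                                      genome.sizes.get(gene.span.chrom))
        seq = genome.seqs[gene.span.chrom]
        promoter_positions = [
            i + 1 for i in range(window.start, window.end - 1) if seq[i:i + 2] == "CG"
        ]
        body_positions = [
            i + 1 for i in range(gene.span.start, gene.span.end - 1) if seq[i:i + 2] == "CG"
        ][:max_body_cpgs]
        for pos in promoter_positions:
            sites.append((gene.span.chrom, pos, promoter_background))
        for pos in body_positions:
            sites.append((gene.span.chrom, pos, body_background))
        if epimutated_gene is not None and gene.symbol == epimutated_gene:
            planted_sites = [(gene.span.chrom, p) for p in promoter_positions]
            if len(planted_sites) < 12:
                raise ValidationError(
                    f"planted promoter of {gene.symbol} has only "
                    f"{len(planted_sites)} CpGs (< 12); enlarge the genome"
                )

    planted = set(planted_sites)

    def sample_table(is_target: bool) -> pd.DataFrame:
        rows = []
        for chrom, pos, ratio in sites:
            for hap in (1, 2):
                p = ratio
                if (
                    is_target
                    and hap == epimutated_haplotype
                    and (chrom, pos) in planted
                ):
                    p = epimutation_ratio
                n_meth = int(rng.binomial(coverage_per_hap, p))
                rows.append((chrom, pos, hap, n_meth, coverage_per_hap - n_meth))
        return pd.DataFrame(rows, columns=meth.METH_COLUMNS)

    controls = [sample_table(False) for _ in range(n_controls)]
    target = sample_table(True)
    manifest = {
        "seed": seed,
        "epimutated_gene": epimutated_gene,
        "epimutated_haplotype": epimutated_haplotype,
        "n_planted_promoter_cpgs": len(planted_sites),
        "n_controls": n_controls,
        "coverage_per_hap": coverage_per_hap,
        "promoter_background": promoter_background,
        "body_background": body_background,
        "epimutation_ratio": epimutation_ratio,
    }
    return MethylationFixture(target=target, controls=controls,
                              genes=list(genes), manifest=manifest)


# ---------------------------------------------------------------------------
# Genotype pairs


@dataclass
class GenotypePairFixture:
    truth: list[GenotypeRecord]
    test: list[GenotypeRecord]
    manifest: dict


def make_genotype_pair(
    seed: int,
    n_sites: int = 10_000,
    error_rate: float | dict[int, float] = 0.02,
    edges: Sequence[float] = DEFAULT_BINS,
    chrom: str = "chr1",
    frac_low_depth: float = 0.0,
) -> GenotypePairFixture:
    """Truth/test genotype call sets with planted per-bin discordance.

    Sites are spread over all MAF bins; truth dosages follow
    Hardy-Weinberg at the site's allele frequency; test dosages are flipped
    to a different value at the planted per-bin rate.  A fraction of truth
    sites can be given low depth to exercise the validation-depth filter.
    """
    if isinstance(error_rate, dict):
        rates = {i: float(error_rate.get(i, 0.0)) for i in range(len(edges) - 1)}
    else:
        rates = {i: float(error_rate) for i in range(len(edges) - 1)}
    if any(not (0 <= r <= 1) for r in rates.values()):
        raise ValidationError("error rates must lie in [0, 1]")
    rng = substream(seed, "genotypes")
    edges = tuple(edges)
    bases = "ACGT"
    truth, test = [], []
    flips = {i: 0 for i in rates}
    counts = {i: 0 for i in rates}
    for i in range(n_sites):
        pos = 100 + 10 * i
        b = int(rng.integers(0, len(edges) - 1))
        lo, hi = edges[b], edges[b + 1]
        maf = float(rng.uniform(lo, hi))
        ref = bases[int(rng.integers(0, 4))]
        alt = bases[(bases.index(ref) + 1 + int(rng.integers(0, 3))) % 4]
        gt = int(rng.binomial(2, maf))
        low_depth = rng.random() < frac_low_depth
        truth.append(GenotypeRecord(chrom, pos, ref, alt, gt, maf,
                                    truth_depth=5 if low_depth else 30,
                                    truth_gq_prob=1.0))
        gt_test = gt
        if rng.random() < rates[b]:
            gt_test = int((gt + 1 + rng.integers(0, 2)) % 3)
            if not low_depth:
                flips[b] += 1
        if not low_depth:
            counts[b] += 1
        test.append(GenotypeRecord(chrom, pos, ref, alt, gt_test, maf))
    manifest = {
        "seed": seed,
        "n_sites": n_sites,
        "edges": list(edges),
        "planted_error": {str(i): rates[i] for i in rates},
        "realized_error": {
            str(i): (flips[i] / counts[i] if counts[i] else None) for i in rates
        },
        "n_per_bin": {str(i): counts[i] for i in rates},
    }
    return GenotypePairFixture(truth=truth, test=test, manifest=manifest)


def write_genotype_vcf(records: Sequence[GenotypeRecord], path,
                       with_truth_format: bool = False) -> None:
    """Minimal single-sample VCF (AF in INFO; GT[, DP, GP] in FORMAT)."""
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AF,Number=A,Type=Float,Description="Panel allele frequency">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if with_truth_format:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
            fh.write('##FORMAT=<ID=GP,Number=G,Type=Float,Description="Genotype probability">\n')
        chroms = sorted({r.chrom for r in records})
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tSAMPLE\n")
        for r in sorted(records, key=lambda x: (x.chrom, x.pos)):
            info = f"AF={r.maf:.6f}"
            if with_truth_format:
                gp = ["0.0", "0.0", "0.0"]
                gp[r.gt] = f"{r.truth_gq_prob:.5f}" if r.truth_gq_prob is not None else "1.0"
                fmt = "GT:DP:GP"
                sample = f"{gt_str[r.gt]}:{r.truth_depth or 30}:{','.join(gp)}"
            else:
                fmt = "GT"
                sample = gt_str[r.gt]
            fh.write(
                f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t100\tPASS\t{info}\t{fmt}\t{sample}\n"
            )


def write_af_table(records: Sequence[GenotypeRecord], path) -> None:
    pd.DataFrame(
        [{"chrom": r.chrom, "pos": r.pos, "ref": r.ref, "alt": r.alt, "af": r.maf}
         for r in records]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# SV callset


@dataclass
class SvCallsetFixture:
    records: list[SvRecord]
    manifest: pd.DataFrame
    simple_repeats: RegionSet


def _largest_intron(gene: GeneModel) -> GenomicInterval | None:
    exons = sorted(gene.transcripts[0].exons, key=lambda e: e.start)
    best = None
    for a, b in zip(exons, exons[1:]):
        if b.start - a.end > 0 and (best is None or b.start - a.end > best.length):
            best = GenomicInterval(a.chrom, a.end, b.start)
    return best


def make_sv_callset(
    seed: int,
    genes: Sequence[GeneModel],
    targets: RegionSet,
    chrom_sizes: dict[str, int],
    primary_contigs: set[str] | None = None,
) -> SvCallsetFixture:
    """One exemplar per elimination rule and pathogenic category plus benign
    decoys, with the intended outcome of each record in the manifest.

    Also fabricates the simple-repeat intervals the rule-(c) exemplars
    need (one inside a target-gene intron, one outside the targets).
    """
    rng = substream(seed, "svs")
    primary = primary_contigs or set(chrom_sizes)
    # a gene with a roomy intron hosts the repeat-containment exemplars
    host = max(
        (g for g in genes if _largest_intron(g) is not None),
        key=lambda g: _largest_intron(g).length,
    )
    intron = _largest_intron(host)
    if intron.length < 1200:
        raise ValidationError("no gene intron large enough for the SV exemplars")
    rep_len = 60
    rep_start = intron.start + intron.length // 2
    repeat_in = GenomicInterval(intron.chrom, rep_start, rep_start + rep_len)
    off_target = targets.complement(chrom_sizes).merge()
    off_iv = max(off_target.intervals, key=lambda iv: iv.length)
    repeat_out = GenomicInterval(
        off_iv.chrom, off_iv.start + off_iv.length // 2,
        off_iv.start + off_iv.length // 2 + rep_len,
    )
    repeats = RegionSet([repeat_in, repeat_out], label="simple_repeats").merge()

    other = next(g for g in genes if g is not host)
    host_cds = sorted(host.cds_region().intervals, key=lambda c: c.start)
    mid_cds = host_cds[len(host_cds) // 2]
    utr5 = sorted(host.transcripts[0].utrs, key=lambda u: u.start)[0]

    records: list[SvRecord] = []
    expect: list[dict] = []

    def add(sv: SvRecord, kept: bool, reasons=(), pathogenic=False, reason="none"):
        records.append(sv)
        expect.append({
            "sv_id": sv.sv_id, "expect_kept": kept,
            "expect_fp_reasons": ",".join(reasons) or ".",
            "expect_pathogenic": pathogenic, "expect_reason": reason,
        })

    def bnd(chrom, pos1):  # 1-based helper
        return SvBreakend(chrom, pos1)

    # rule (a): breakend on a non-primary contig
    add(SvRecord("sv_decoy", TRANSLOCATION, bnd("chrUn_decoy", 500),
                 bnd(mid_cds.chrom, mid_cds.start + 2)),
        kept=False, reasons=("nonprimary_contig",))
    # rule (b): both breakends off-target
    far = off_iv.start + off_iv.length // 4
    add(SvRecord("sv_offtarget", DELETION, bnd(off_iv.chrom, far + 1),
                 bnd(off_iv.chrom, far + 400)),
        kept=False, reasons=("no_breakend_in_target",))
    # rule (c): deletion contained in a padded repeat
    add(SvRecord("sv_del_in_repeat", DELETION,
                 bnd(repeat_in.chrom, repeat_in.start + 6),
                 bnd(repeat_in.chrom, repeat_in.end - 5)),
        kept=False, reasons=("contained_in_simple_repeat",))
    # rule (c): insertion point inside a padded repeat
    add(SvRecord("sv_ins_in_repeat", INSERTION,
                 bnd(repeat_in.chrom, repeat_in.start + rep_len // 2),
                 bnd(repeat_in.chrom, repeat_in.start + rep_len // 2),
                 inserted_seq=random_seq(rng, 120)),
        kept=False, reasons=("contained_in_simple_repeat",))
    # rule (c): duplication contained in a padded repeat
    add(SvRecord("sv_dup_in_repeat", DUPLICATION,
                 bnd(repeat_in.chrom, repeat_in.start + 3),
                 bnd(repeat_in.chrom, repeat_in.end - 2)),
        kept=False, reasons=("contained_in_simple_repeat",))
    # pathogenic deletion: spans a CDS exon
    add(SvRecord("sv_del_cds", DELETION, bnd(mid_cds.chrom, mid_cds.start - 200),
                 bnd(mid_cds.chrom, mid_cds.end + 200)),
        kept=True, pathogenic=True, reason="deletion_hits_cds")
    # benign deletion: intronic, escapes repeat containment
    add(SvRecord("sv_del_intron", DELETION, bnd(intron.chrom, intron.start + 30),
                 bnd(intron.chrom, intron.start + 330)),
        kept=True, pathogenic=False)
    # pathogenic duplication: breakend in CDS, span covers a whole CDS exon
    add(SvRecord("sv_dup_cds", DUPLICATION, bnd(mid_cds.chrom, mid_cds.start - 150),
                 bnd(mid_cds.chrom, mid_cds.end + 150)),
        kept=True, pathogenic=True, reason="duplication_alters_cds")
    # benign duplication: confined to a UTR
    add(SvRecord("sv_dup_utr", DUPLICATION, bnd(utr5.chrom, utr5.start + 3),
                 bnd(utr5.chrom, utr5.end - 1)),
        kept=True, pathogenic=False)
    # pathogenic inversion: one breakend in coding gene body
    add(SvRecord("sv_inv_gene", INVERSION, bnd(mid_cds.chrom, mid_cds.start + 5),
                 bnd(mid_cds.chrom, mid_cds.end + 2500)),
        kept=True, pathogenic=True, reason="disrupts_gene_body")
    # benign inversion: both breakends in the target margin, outside genes
    margin_pos = host.span.end + 2000
    add(SvRecord("sv_inv_margin", INVERSION, bnd(host.span.chrom, margin_pos),
                 bnd(host.span.chrom, margin_pos + 800)),
        kept=True, pathogenic=False)
    # pathogenic translocation: breakend in the other gene's CDS
    other_cds = sorted(other.cds_region().intervals, key=lambda c: c.start)[0]
    partner_chrom = next(c for c in sorted(chrom_sizes) if c != other_cds.chrom)
    add(SvRecord("sv_tra_gene", TRANSLOCATION, bnd(other_cds.chrom, other_cds.start + 4),
                 bnd(partner_chrom, 1500)),
        kept=True, pathogenic=True, reason="disrupts_gene_body")
    # pathogenic single breakend: inside a target gene intron
    add(SvRecord("sv_bnd_gene", SINGLE_BREAKEND, bnd(intron.chrom, intron.start + 700)),
        kept=True, pathogenic=True, reason="single_breakend_in_gene")
    # benign single breakend: in the margin, outside gene spans
    add(SvRecord("sv_bnd_margin", SINGLE_BREAKEND, bnd(host.span.chrom, margin_pos + 300)),
        kept=True, pathogenic=False)
    # kept deletion that merely overlaps a repeat (one end outside)
    add(SvRecord("sv_del_overlap_repeat", DELETION,
                 bnd(repeat_in.chrom, repeat_in.start - 200),
                 bnd(repeat_in.chrom, repeat_in.start + 20)),
        kept=True, pathogenic=False)

    return SvCallsetFixture(
        records=records,
        manifest=pd.DataFrame(expect),
        simple_repeats=repeats,
    )


# ---------------------------------------------------------------------------
# Alignment summaries


@dataclass
class AlignmentFixture:
    alignments: list[ReadAlignmentSummary]
    manifest: dict


def make_alignment_summaries(
    seed: int,
    targets: RegionSet,
    chrom_sizes: dict[str, int],
    enrichment: float = 10.0,
    n50_on: int = 9_000,
    n50_off: int = 600,
    n_reads: int = 10_000,
    sigma: float = 0.5,
) -> AlignmentFixture:
    """Read placements reproducing the requested enrichment and N50s.

    Read lengths are log-normal with the scale chosen so the
    length-weighted median (the N50 of a large sample) matches the request;
    the on/off read-count split is solved from the requested depth ratio.
    """
    if enrichment <= 0:
        raise ValidationError("enrichment must be > 0")
    rng = substream(seed, "alignments")
    targets = targets.merge()
    t_bp = targets.total_bp
    off = targets.complement(chrom_sizes).merge()
    o_bp = off.total_bp
    mu_on = np.log(n50_on) - sigma**2
    mu_off = np.log(n50_off) - sigma**2
    mean_on = float(np.exp(mu_on + sigma**2 / 2))
    mean_off = float(np.exp(mu_off + sigma**2 / 2))
    ratio = enrichment * (t_bp / o_bp) * (mean_off / mean_on)
    n_on = int(round(n_reads * ratio / (1 + ratio)))
    n_off = n_reads - n_on

    def place(region_set: RegionSet, lengths: np.ndarray, prefix: str):
        ivs = region_set.intervals
        weights = np.array([iv.length for iv in ivs], dtype=float)
        weights /= weights.sum()
        picks = rng.choice(len(ivs), size=len(lengths), p=weights)
        out = []
        for i, (pick, length) in enumerate(zip(picks, lengths)):
            iv = ivs[pick]
            length = max(50, int(length))
            span = min(length, iv.length)
            start = iv.start + int(rng.integers(0, iv.length - span + 1))
            out.append(ReadAlignmentSummary(
                f"{prefix}{i}", iv.chrom, start, start + span, length))
        return out

    alns = place(targets, rng.lognormal(mu_on, sigma, n_on), "on_")
    alns += place(off, rng.lognormal(mu_off, sigma, n_off), "off_")
    manifest = {
        "seed": seed,
        "enrichment": enrichment,
        "n50_on": n50_on,
        "n50_off": n50_off,
        "n_on": n_on,
        "n_off": n_off,
        "target_bp": t_bp,
        "offtarget_bp": o_bp,
    }
    return AlignmentFixture(alignments=alns, manifest=manifest)


def write_alignment_tsv(alns: Sequence[ReadAlignmentSummary], path) -> None:
    with open(path, "w") as fh:
        for a in alns:
            fh.write(f"{a.read_id}\t{a.chrom}\t{a.aln_start}\t{a.aln_end}"
                     f"\t{a.read_length}\t{a.primary}\n")


# ---------------------------------------------------------------------------
# Annotated SNV/indel VCF


@dataclass
class SnvFixture:
    vcf_text: str
    manifest: dict


def make_annotated_variants(
    seed: int,
    genes: Sequence[GeneModel],
    simple_repeats: RegionSet,
    segdups: RegionSet,
) -> SnvFixture:
    """Annotated variant exemplars exercising every prioritization rule.

    Includes variants that fail the quality, region, and common-frequency
    filters, plus survivors carrying each pathogenicity label (and one
    double-labeled LoF + splice-site variant).  The manifest records the
    expected surviving label sets.
    """
    rng = substream(seed, "snv")
    gene = genes[0]
    cds = sorted(gene.cds_region().intervals, key=lambda c: c.start)[0]
    chrom = cds.chrom
    inside = cds.start + 5  # 0-based positions inside the gene span
    bases = "ACGT"

    def pos1(offset):
        return inside + offset + 1

    rows = []
    expected: dict[str, list[str]] = {}

    def add(vid, pos, qual, info, expect_labels=None):
        ref = bases[int(rng.integers(0, 4))]
        alt = bases[(bases.index(ref) + 1) % 4]
        rows.append((chrom, pos, vid, ref, alt, qual, info))
        if expect_labels is not None:
            expected[vid] = sorted(expect_labels)

    add("v_lowqual", pos1(0), 8.0, "CLNSIG=Pathogenic")          # quality <= 10
    add("v_boundary_qual", pos1(2), 10.0, "CLNSIG=Pathogenic")   # exactly 10: dropped
    add("v_common", pos1(4), 50.0, "gnomAD_AF=0.0150;CLNSIG=Pathogenic")
    add("v_clinvar", pos1(6), 50.0, "CLNSIG=Pathogenic;gnomAD_AF=0.0001",
        expect_labels=["known_pathogenic"])
    add("v_clinvar_combined", pos1(8), 50.0,
        "CLNSIG=Pathogenic/Likely_pathogenic", expect_labels=["known_pathogenic"])
    add("v_lof", pos1(10), 50.0, "LoF=HC", expect_labels=["lof"])
    add("v_lof_lc", pos1(12), 50.0, "LoF=LC")  # low confidence: no label
    add("v_spliceai", pos1(14), 50.0,
        "SpliceAI_DS_AG=0.50;SpliceAI_DS_AL=0.10;SpliceAI_DS_DG=0.00;SpliceAI_DS_DL=0.20",
        expect_labels=["splicing"])
    add("v_splice_site_lof", pos1(16), 50.0,
        "Consequence=splice_donor_variant;LoF=HC", expect_labels=["lof", "splicing"])
    add("v_benign", pos1(18), 50.0, "CLNSIG=Benign")
    # in a simple repeat: region filter removes it
    rep = simple_repeats.intervals[0]
    add("v_in_repeat", rep.start + 5, 50.0, "CLNSIG=Pathogenic")
    # outside every gene span entirely
    add("v_intergenic", max(2, gene.span.start - 3000), 50.0, "CLNSIG=Pathogenic")

    header = (
        "##fileformat=VCFv4.2\n"
        '##INFO=<ID=gnomAD_AF,Number=1,Type=Float,Description="gnomAD AF">\n'
        '##INFO=<ID=TOMMO_AF,Number=1,Type=Float,Description="ToMMo AF">\n'
        '##INFO=<ID=CLNSIG,Number=1,Type=String,Description="ClinVar significance">\n'
        '##INFO=<ID=LoF,Number=1,Type=String,Description="LOFTEE flag">\n'
        '##INFO=<ID=Consequence,Number=1,Type=String,Description="SO terms">\n'
        '##INFO=<ID=SpliceAI_DS_AG,Number=1,Type=Float,Description="DS">\n'
        '##INFO=<ID=SpliceAI_DS_AL,Number=1,Type=Float,Description="DS">\n'
        '##INFO=<ID=SpliceAI_DS_DG,Number=1,Type=Float,Description="DS">\n'
        '##INFO=<ID=SpliceAI_DS_DL,Number=1,Type=Float,Description="DS">\n'
        f"##contig=<ID={chrom}>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
    )
    body = "".join(
        f"{c}\t{p}\t{vid}\t{ref}\t{alt}\t{q}\t.\t{info}\n"
        for c, p, vid, ref, alt, q, info in sorted(rows, key=lambda r: r[1])
    )
    n_labels = {"known_pathogenic": 0, "lof": 0, "splicing": 0}
    for labels in expected.values():
        for lab in labels:
            n_labels[lab] += 1
    manifest = {
        "seed": seed,
        "expected_labels": expected,
        "expected_distinct": len(expected),
        "expected_per_label": n_labels,
    }
    return SnvFixture(vcf_text=header + body, manifest=manifest)


# ---------------------------------------------------------------------------
# FASTA / bundle output


def write_fasta(seqs: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name in sorted(seqs):
            fh.write(f">{name}\n")
            seq = seqs[name]
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")


@dataclass
class StudyFixtures:
    """All in-memory artifacts of one fixture study, built from one seed."""

    seed: int
    genome: SyntheticGenome
    genes: list[GeneModel]
    gtf_text: str
    gene_manifest: dict
    design: object  # TargetDesign
    mei: MeiFixture
    methylation: MethylationFixture
    genotypes: GenotypePairFixture
    svs: SvCallsetFixture
    alignments: AlignmentFixture
    snv: SnvFixture
    simple_repeats: RegionSet
    segdups: RegionSet

    def manifest(self) -> dict:
        return {
            "seed": self.seed,
            "genome": self.genome.manifest,
            "genes": self.gene_manifest,
            "target_total_bp": self.design.total_bp,
            "mei": self.mei.manifest,
            "methylation": self.methylation.manifest,
            "genotypes": self.genotypes.manifest,
            "sv": self.svs.manifest.to_dict(orient="records"),
            "alignments": self.alignments.manifest,
            "snv": self.snv.manifest,
        }


def build_study(seed: int) -> StudyFixtures:
    """Generate every fixture of one synthetic study in memory."""
    from . import targets as targets_mod

    genome = make_genome(seed, lengths={"chr1": 200_000, "chr2": 120_000})
    genes, gtf_text, gene_manifest = make_gene_annotation(seed, genome, n_genes=8)
    design = targets_mod.build_target_regions(genes, margin=10_000,
                                              chrom_sizes=genome.sizes)
    mei_fx = make_mei_event(
        seed, genome, make_repeat_library(seed),
        avoid=RegionSet([g.span for g in genes]).union(design.regions),
    )
    meth_fx = make_methylation_dataset(
        seed, genes, genome, epimutated_gene=genes[0].symbol, epimutated_haplotype=2
    )
    geno_fx = make_genotype_pair(seed, n_sites=4000)
    sv_fx = make_sv_callset(seed, genes, design.regions, genome.sizes)
    aln_fx = make_alignment_summaries(seed, design.regions, genome.sizes,
                                      n_reads=6000)
    simple_repeats = genome.repeat_mask.union(sv_fx.simple_repeats)
    segdups = RegionSet([GenomicInterval("chr2", 1000, 2000)], label="segdups")
    snv_fx = make_annotated_variants(seed, genes, simple_repeats, segdups)
    return StudyFixtures(
        seed=seed, genome=genome, genes=genes, gtf_text=gtf_text,
        gene_manifest=gene_manifest, design=design, mei=mei_fx,
        methylation=meth_fx, genotypes=geno_fx, svs=sv_fx, alignments=aln_fx,
        snv=snv_fx, simple_repeats=simple_repeats, segdups=segdups,
    )


ARTIFACTS = ("bundle", "genome", "genes", "mei", "methylation", "genotypes",
             "svs", "alignments", "snvs")


def write_artifact(study: StudyFixtures, artifact: str, outdir) -> None:
    """Write one artifact's files (or all of them for "bundle")."""
    from .regions import write_bed

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    everything = artifact == "bundle"

    if everything or artifact == "genome":
        write_fasta(study.genome.seqs, outdir / "genome.fa")
        with open(outdir / "chrom_sizes.tsv", "w") as fh:
            for chrom in sorted(study.genome.sizes):
                fh.write(f"{chrom}\t{study.genome.sizes[chrom]}\n")
        write_bed(study.simple_repeats.merge(), outdir / "simple_repeats.bed")
        write_bed(study.segdups, outdir / "segdups.bed")
    if everything or artifact == "genes":
        (outdir / "genes.gtf").write_text(study.gtf_text)
        with open(outdir / "gene_list.txt", "w") as fh:
            for g in study.genes:
                fh.write(g.symbol + "\n")
        write_bed(study.design.regions, outdir / "targets.bed")
    if everything or artifact == "mei":
        library_to_fasta(study.mei.lib, outdir / "repeat_library.fa")
        write_fasta({"insertion": study.mei.call.inserted_seq},
                    outdir / "insertion.fa")
        with open(outdir / "insertion_site.tsv", "w") as fh:
            fh.write("name\tchrom\tpos\ninsertion\t"
                     f"{study.mei.call.site.chrom}\t{study.mei.call.site.pos}\n")
        write_bed(study.genome.repeat_mask.merge(), outdir / "mei_repeat_mask.bed")
    if everything or artifact == "methylation":
        meth_dir = outdir / "methylation"
        meth_dir.mkdir(exist_ok=True)
        study.methylation.target.to_csv(meth_dir / "target.tsv", sep="\t", index=False)
        for i, df in enumerate(study.methylation.controls):
            df.to_csv(meth_dir / f"control_{i:02d}.tsv", sep="\t", index=False)
    if everything or artifact == "genotypes":
        write_genotype_vcf(study.genotypes.truth, outdir / "truth.vcf",
                           with_truth_format=True)
        write_genotype_vcf(study.genotypes.test, outdir / "test.vcf")
        write_af_table(study.genotypes.truth, outdir / "panel_af.tsv")
    if everything or artifact == "svs":
        sv_rows = []
        for sv in study.svs.records:
            sv_rows.append({
                "sv_id": sv.sv_id, "sv_type": sv.sv_type,
                "chrom1": sv.bp1.chrom, "pos1": sv.bp1.pos,
                "dir1": sv.bp1.orientation,
                "chrom2": sv.bp2.chrom if sv.bp2 else ".",
                "pos2": sv.bp2.pos if sv.bp2 else ".",
                "dir2": sv.bp2.orientation if sv.bp2 else ".",
                "inserted_seq": sv.inserted_seq or "",
            })
        pd.DataFrame(sv_rows).to_csv(outdir / "svs.tsv", sep="\t", index=False)
    if everything or artifact == "alignments":
        write_alignment_tsv(study.alignments.alignments, outdir / "alignments.tsv")
    if everything or artifact == "snvs":
        (outdir / "snvs.vcf").write_text(study.snv.vcf_text)

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(study.manifest(), fh, indent=1)


def make_bundle(seed: int, outdir) -> dict:
    """Write a complete fixture bundle (genome, annotation, masks, per-stage
    inputs) plus manifest.json; returns the manifest."""
    study = build_study(seed)
    write_artifact(study, "bundle", outdir)
    return study.manifest()
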