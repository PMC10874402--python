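# taslrs

Downstream analysis for **target adaptive sampling long-read sequencing
(TAS-LRS)** of hereditary cancer genomes.

Adaptive sampling is a computational enrichment mode of nanopore
sequencing: molecules that do not match a target region list are ejected
from the pore in real time, yielding deep coverage with long reads over a
gene panel and shallow genome-wide coverage from the rejected reads.  A
single run therefore supports three very different analyses at once —
deep variant interpretation on the panel, genome-wide common-SNP
genotyping from the off-target reads, and read-level CpG methylation.
This package implements the interpretation layer that sits downstream of
basecalling, alignment, and the variant/methylation callers:

* **Target design** — build the panel BED from gene annotation: maximal
  span over all transcripts per gene, ±10 kbp margin, clipped, merged,
  plus manual extension regions (`taslrs.targets`).
* **Coverage QC** — on/off-target mean depth, enrichment ratio, and
  per-class read N50 (`taslrs.coverage`).
* **SNV/indel prioritization** — quality > 10, gene-span region
  restriction excluding simple-repeat/segmental-duplication masks,
  population AF < 1% (gnomAD/ToMMo-style sources), then three
  pathogenicity labels: ClinVar Pathogenic/Likely pathogenic, LOFTEE
  high-confidence loss of function, and splicing (essential GT-AG
  consequence or SpliceAI delta score ≥ 0.50) (`taslrs.snv`).
* **SV post-filtering** — the false-positive elimination filter
  (non-primary contigs; no breakend in targets; deletion/insertion/
  duplication contained in a simple repeat ±10 bp) and putative-pathogenic
  extraction (deletions hitting CDS; duplications with a non-UTR breakend
  covering a complete CDS exon; inversions/translocations with a non-UTR
  breakend; single breakends inside a target gene) (`taslrs.sv`).
* **Mobile-element insertion anatomy** — target-site duplication from the
  flanks, 3' poly-A tract, segmentation against a repeat consensus
  library (SVA subfamilies, L1, Alu), source-locus tracing with 3'
  transduction and its AATAAA polyadenylation signal, and the 5'
  (CCCTCT)n hexamer head whose loss marks a no-longer-mobile element
  (`taslrs.mei`).
* **Allele-specific methylation (epimutation) screen** — site classes
  from a 10-sample control panel (ratio 0–0.2 / 0.8–1 in *all* controls),
  two-sided Fisher exact calls per target haplotype (hyper: ratio > 0.2
  and p ≤ 0.05 at normally unmethylated sites; hypo mirrored), and gene
  flagging over the 2000 bp promoter window when mean −log10(p) ≥ 4.5 or
  ≥ 10 aberrant CpGs (`taslrs.methylation`).
* **Genotype concordance** — dosage concordance of an imputed call set
  against a depth/confidence-filtered truth set, stratified by
  reference-panel minor allele frequency over the bins
  0.000/0.001/0.002/0.005/0.010/0.050/0.100/0.200/0.500
  (`taslrs.concordance`).
* **Synthetic fixtures** — deterministic generators for every input
  (genome, annotation, repeat library, planted retrotransposition events,
  methylation count tables, genotype pairs, SV callsets, alignment
  summaries) with manifests recording the planted ground truth
  (`taslrs.simulate`).

Patient data for such studies are controlled-access; everything here runs
on the synthetic fixtures, and every fixture records what was planted so
recovery can be asserted exactly.

## Worked example

Generate a fixture bundle and run the whole pipeline on it:

```sh
taslrs simulate bundle --seed 12 --out bundle12
taslrs run-all --bundle bundle12 --out out12
```

which prints (seed 12):

```
target regions: 4 intervals, 215936 bp
on-target 128.01x, off-target 12.80x, enrichment 10.00
putative pathogenic variants: 5
15 SVs: 10 kept, 5 putative pathogenic
insertion: TSD 14 bp, polyA 24 bp, transduction 82 bp, source chr2:36104-38436
flagged gene x haplotype: [('GENE1', 2)]
compared 4000 sites over 8 MAF bins
pipeline complete
```

Reading the output: the enrichment of 10.00 is the ratio of mean on- to
off-target depth (the bundle plants 10×); the five prioritized variants
are the fixture's planted ClinVar/LoF/splicing exemplars (one variant
carries two labels, so labels sum to six); ten of fifteen SVs survive the
false-positive filter and five are putative pathogenic, one per category
plus a translocation; the insertion is decomposed into two SVA_F segments
followed by an 82 bp 3' transduction that pins its source locus, a 24 bp
poly-A tail, and a 14 bp target-site duplication; and the methylation
screen flags exactly the planted haplotype-2 promoter hypermethylation of
GENE1.  `bundle12/manifest.json` holds every planted value for
comparison.

The same stages are available individually (`taslrs build-targets`,
`qc`, `prioritize-snv`, `filter-sv`, `annotate-mei`, `epimutation`,
`concordance`) and as library functions.

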