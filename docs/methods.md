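# Methods

This note records the models, rules, and numerical choices behind each
stage, what the synthetic data do and do not emulate, and the known
limitations.

## Coordinates and regions

All internal coordinates are 0-based half-open; 1-based inclusive values
(VCF and GTF positions, coordinates quoted in running text) are converted
only at the I/O boundary via `GenomicInterval.from_one_based` /
`to_one_based`, so the conversion composes to identity.  Chromosome names
match by exact string ("chr6" ≠ "6"); aliasing must be explicit.
`RegionSet` keeps records as supplied and answers queries against a
lazily merged per-chromosome index; merging joins abutting intervals, so
`total_bp` is the size of the per-base union.  BED strand defaults to
unstranded below six columns.  No liftover and no alt-haplotype
awareness beyond contig name lists.

## Target design

A gene's footprint is the maximal extent over all of its transcripts.
Targets are those spans padded symmetrically by a margin (default
10 kbp), clipped at chromosome bounds, unioned with manual extension
regions supplied as a BED side file (the mechanism for adding, e.g., an
alternative first exon missing from an annotation release), and merged.
Whether overlapping genes are merged before or after padding does not
change the final merged output.  The published panel size for a specific
annotation release is not reproduced here, as it depends on that
database version.

## Coverage QC

A read is on-target when its primary alignment overlaps the targets by
at least 1 bp.  Mean depth over a region set is (total aligned bp falling
in the set) / (set size); secondary/supplementary alignments are excluded
so split reads count once, and the off-target region is the genome
complement over a supplied chromosome-sizes table.  Enrichment is the
depth ratio, reported as +inf with a warning when off-target coverage is
zero.  N50 is the largest L such that reads of length ≥ L contain at
least half of all bases; it is computed over full read lengths by
default, with a switch for aligned-span lengths, since either convention
is defensible for per-class statistics.

## SNV/indel prioritization

Four pure predicates applied in sequence (order does not change the
surviving set): caller quality strictly greater than 10 (records at
exactly 10 are removed); position inside the maximal gene spans and
outside simple-repeat and segmental-duplication masks at margin 0
(distinct from the padded sequencing targets); population allele
frequency below 0.01 — the boundary itself is "common" — with OR
semantics across sources (any source at/above threshold removes the
variant; a flag switches to AND) and absent sources counted as 0.
Survivors receive up to three labels: ClinVar Pathogenic/Likely
pathogenic matched case-insensitively including the slash-combined form;
splicing, from an essential GT-AG consequence term
(splice_acceptor/donor_variant) or a SpliceAI delta score ≥ 0.50,
interpreting "delta score" as the conventional headline max of the four
(AG, AL, DG, DL) values; and LOFTEE high-confidence LoF.  Splicing-
database memberships are carried as informational tags only.  Distinct
variant totals follow set union, so categories may overlap.

## SV post-filtering

Elimination rules: (a) any breakend on a contig outside the primary set;
(b) no breakend inside the targets; (c) deletions, insertions and tandem
duplications **fully contained** in one simple-repeat interval padded by
10 bp — containment of both breakends (the single insertion point for
insertions), not mere overlap, since overlap would also discard large
genuine deletions that happen to cross a repeat.  The padded repeat
intervals are taken from the normalized mask, so adjacent repeat
annotations that merge are treated as one interval.  All fired reasons
are recorded; a record is kept only when none fire, and re-filtering
survivors is the identity.

Pathogenic categories for kept records, each tied to its SV type (hence
exactly one reason per call): deletions whose span intersects any CDS
interval; duplications with at least one breakend inside a gene
excluding UTRs whose span covers at least one complete CDS interval (the
minimal reading of "amplified regions span the coding sequences");
inversions/translocations with a breakend inside a gene excluding UTRs;
single breakends inside a gene span (intronic hits count; a switch
restricts to non-UTR regions).  Matched-control/panel-of-normals
subtraction happens inside the SV caller and is out of scope; this layer
consumes the caller's output.

## Mobile-element insertion anatomy

Order of operations: TSD → TSD trim → strand normalization → poly-A →
library segmentation → source/transduction tracing → hexamer head.

*TSD.*  The longest 5–50 bp string that is simultaneously a suffix of
(left flank + insertion) and a prefix of the right flank, or — the
mirrored caller convention — a suffix of the left flank and a prefix of
(insertion + right flank), allowing one mismatch, ties to the longer.
If the insertion's terminal bases duplicate the TSD they are trimmed
before further analysis, making the module caller-agnostic about where
the duplicated bases are reported.  Strand is normalized after trimming
(a minus-strand event carries the tail as a 5' poly-T head, which the
TSD would otherwise hide); the annotation records the chosen strand.

*Poly-A.*  The longest 3'-terminal window with non-A fraction ≤ 0.1
whose 5'-most base is an A (a window opening on a mismatch is never the
canonical tail); 0 below 10 bp.

*Segmentation.*  Exact k-mer (k = 15) diagonal runs against each library
consensus are chained into candidate segments, selected greedily by
length with overlap trimming (chance 1–2 bp extensions and the hexamer
head shared by all SVA subfamilies produce small overlaps; the larger
remaining side is kept when a selected segment splits a candidate),
subject to ≥ 100 bp length and ≥ 80% identity (edlib global edit
distance).  Gaps are emitted as unclassified so segments always tile the
trimmed insertion.  The internal seed-and-chain aligner is deliberately
desk-scale; a full local aligner can be substituted behind the same HSP
interface.

*Source and transduction.*  The poly-A-stripped body is aligned to the
reference; the best co-linear chain defines the source locus.  The
transduction is the 3'-terminal aligned stretch outside the repeat mask
but genomically contiguous (within 1 kb) with the masked element; its
length is taken from the genome side, and the query-side segment is
clamped to the observed gap.  The polyadenylation signal is the exact
motif AATAAA inside the transduction (variant signals out of scope).

*Hexamer head.*  ≥ 2 tandem CCCTCT copies starting within the first
100 bp of the 5'-most repeat segment; absence marks the element as 5'
truncated (and hence no longer mobilizable).

## Epimutation screen

Per CpG and control sample, the methylation ratio is methylated /
(methylated + unmethylated) calls, haplotypes summed within a sample.  A
site is *normally unmethylated* when every control has ratio in
[0, 0.2] (closed bounds, as printed) with coverage ≥ 5 — the coverage
floor is this package's addition, since a zero-coverage control would
vacuously satisfy any band — and *normally methylated* for [0.8, 1].
Target haplotypes are tested by a two-sided Fisher exact test against
the controls pooled over samples and haplotypes (a switch enables
haplotype-matched pooling): hyper requires a normally unmethylated site,
ratio strictly above 0.2, p ≤ 0.05; hypo mirrors it at ≤ 0.8.  The
two-sided p is the point-probability sum — all fixed-margin tables no
more probable than the observed one — computed from scipy's
hypergeometric pmf with a 1e-7 relative tie guard; the test suite checks
it against exact integer-arithmetic enumeration to 1e-12.  No
site-level multiple-testing correction is applied; the gene-level
thresholds are the stringency mechanism.  Genes are scored per
haplotype over the 2000 bp window upstream of the outermost TSS
(strand-aware, clipped): flagged when the mean −log10(p) over aberrant
promoter CpGs reaches 4.5 or when 10 such CpGs accumulate; a gene with
no aberrant site is never flagged.

A consequence worth knowing: with one aberrant site, the mean rule
reduces to that single site's p-value, so one extreme sampling
fluctuation at a background CpG (e.g. 5 of 10 reads methylated where
~3% is expected) can flag a gene on its own.  At 10× per-haplotype
coverage this happens for roughly 3 in 10,000 background
gene-haplotypes.  This is a property of the screen's printed thresholds,
not of the implementation; real applications of such screens likewise
surface occasional incidental flags for follow-up review.

## Genotype concordance

Biallelic records are matched on (chrom, pos, ref, alt); unsplit
multi-allelics are rejected with instructions to normalize first.  Truth
records are filtered to depth ≥ 8 and genotype confidence ≥ 0.9999 (a
GQ-derived probability or a likelihood field; exact equivalence to any
external tool's likelihood handling is not claimed).  Comparison is by
alt-allele dosage (0/1/2), so phase switches are not errors.  MAF comes
from the reference-panel annotation (a cohort of one cannot estimate
it); bins are half-open on stated edges with the last bin closed at 0.5.
Genotype concordance (% identical dosages) is symmetric in truth/test;
non-reference concordance — restricted to sites where either call is
non-reference — is not.  Empty bins report absent, not 0.

## Synthetic fixtures

Each generator draws from a labeled child stream of the master seed
(`SeedSequence(seed, spawn_key=(crc32(label),))`), so generators are
mutually independent and byte-reproducible.  Defaults mirror the
magnitudes of a real adaptive-sampling study: ~10× enrichment, 9 kb
on-target and 0.6 kb off-target N50 (log-normal lengths, σ = 0.5, scale
set so the length-weighted median matches the requested N50), 10
methylation controls at 20× (10× per haplotype), promoter background
methylation 3% (realistic for unmethylated CpG islands) and gene-body
85%, planted epimutation ratio 0.9, genotype error 2%, and
retrotransposition events built exactly as the anatomy implies: a source
locus (element copies + unique tail carrying AATAAA) written into the
genome and masked, and an insertion = truncated element + tail + poly-A
+ duplicated site bases.  The tail's last few bases (poly-A length / 6
+ 3) are forced non-A so the planted poly-A boundary is unambiguous
under the detector's 10% mismatch budget — the construction's stand-in
for a cleavage site.

What the fixtures do **not** emulate: sequencing error and mapping
ambiguity (alignments are exact), repeat polymorphism and diverged
element copies (library hits are exact slices), CpG-density structure
of real promoters (CpGs fall at random-genome CG dinucleotides),
linkage between sites, and imputation-specific error structure
(genotype errors are independent flips).  Passing recovery tests
therefore demonstrates correctness of the decision rules and the
anatomy reconstruction at zero noise, not robustness to real-data noise.

## Problem sizes

The test suite and acceptance script run on two-chromosome genomes of
200 + 120 kb with 8 genes, 100 mobile-element events on 40 kb genomes,
20 methylation datasets (~2,500 site-haplotype calls each), 10⁴ Fisher
tables with margins ≤ 200, 10⁴ genotype sites, and 10⁴ simulated reads —
sizes chosen so the whole suite completes in well under a minute of
compute per stage while every bin, rule, and category stays populated.
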