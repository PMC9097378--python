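# Methods

## Scope and data model

`telocus` works downstream of the aligners: it consumes genome FASTA, gene
GFF3, TE BED (+ canonical-length and sub-feature tables) and SAM/BAM
alignments, and never runs an aligner itself. All coordinates are 0-based
half-open internally; GFF3 and SAM are converted at the I/O boundary.

A TE locus carries its family, superfamily, the family's canonical element
length, optional structural sub-features (5′/3′ LTR and INT domain for LTR
retrotransposons, transposase ORF for TIR DNA transposons) and a
structurally-intact flag from the annotation. Locus *integrity* is genomic
span divided by canonical length — internal deletions are deliberately
ignored, matching a length-based notion of integrity; loci above 0.9 are
"full-length". Multi-isoform genes are collapsed to their longest
transcript's exon chain (the annotation rarely marks a canonical isoform, and
the longest transcript gives the most inclusive gene unit).

## Expression-candidate calling (short reads)

Three filters run over every annotated locus; the candidate pool is their
union. All thresholds are strict inequalities and live in `AnalysisConfig`.

1. **Unique-read filter.** A unique-mapping alignment (NH tag = 1, falling
   back to MAPQ ≥ 10 when the tag is absent) counts toward a locus only if
   that locus is the sole TE it overlaps — the intersection-nonempty rule —
   so each read contributes at most once. Pass: count > `min_reads` (10).
2. **Coverage filter.** Every reported alignment, unique or multi-mapping,
   counts once at each locus it overlaps; mean depth averages only over
   covered bases (so sparse loci are not diluted by uncovered positions).
   Pass: total > 10 **and** mean depth > 5.
3. **Dangler filter.** A dangler is a uniquely mapped genome alignment whose
   mate aligned to the canonical TE library. It is assigned to a locus side
   when it lies entirely outside the locus, within `dangler_window` (1000 bp)
   of that boundary, and points toward the locus (+ strand on the left,
   − strand on the right). Alignments crossing a locus boundary are dropped
   (`exclude_tails`). Pass: danglers on at least one side > 10
   (`dangler_side_mode="any"`; "both" is available — the stricter reading of
   "on either side") **and** internal reads > 10.

Candidates with any unique-read support are *trackable*: their expression is
attributable to that specific locus because the reads span a distinguishing
polymorphism. Counting is per mate (each aligned mate is one unit) across
all three filters, keeping the counts mutually comparable.

## Genomic compartments and location bias

Gene units tile into exons and introns; N-flanks cover `flank_width`
(2000 bp) upstream of the transcription start and C-flanks the same
downstream of the stop, strand-aware and truncated at chromosome ends.
Overlapping genes may stack labels. A locus touching any genic label is
genic; its single location label resolves by priority exon > intron >
N-flank > C-flank, among genes the largest total overlap wins, and exact
ties go to the lower gene start (then gene id) for determinism. For DETE–DEG
pairing a separate enumeration keeps *every* overlapping gene, since one TE
may pair with several genes.

A gene counts as expressed when FPKM > 1; in long-read mode both ONT TPM > 1
and Illumina FPKM > 1 are required (the conjunction of the two platforms).

Location bias is a chi-square goodness-of-fit test,
X² = Σ (Oᵢ − N·pᵢ)² / (N·pᵢ) with df = k − 1, where the expected proportions
come from the full annotated locus set restricted to the same category
universe. Significance is declared at p < 0.01. A category with zero
expected count raises an error instructing a merge rather than silently
producing an infinite statistic.

## LTR insertion dating

The LTR pair of a structurally intact locus is globally aligned
(match +1, mismatch −1, gap open −5, gap extend −1); gap and N columns are
excluded when counting the transition proportion P and transversion
proportion Q. The Kimura two-parameter distance is

    K = −(1/2) ln[(1 − 2P − Q) √(1 − 2Q)]

undefined (saturated) when 1 − 2P − Q ≤ 0 or 1 − 2Q ≤ 0; saturated loci are
excluded from dating rather than clamped. Insertion time is T = K / (2r)
(each LTR accumulates substitutions independently), reported in MYA. The
substitution rate r defaults to 1.3×10⁻⁸ substitutions/site/year — a
commonly used plant rate — and is configuration-owned; every output records
the r used. Per-family amplification peaks are the argmax of a Gaussian KDE
(Silverman bandwidth) on a 512-point grid over [0, max(T)], computed only
for families with ≥ 10 dated loci; exact ties resolve to the smallest time,
and a degenerate all-equal sample returns that value directly.

## Differential expression and concordance

The DE engine is a documented stand-in for a negative-binomial GLM:
median-of-ratios size factors, log₂ fold-changes on normalised means with a
pseudocount of 1, and a two-sample test on log₂(norm + 1) counts whose
per-feature pooled variances are shrunk toward the across-feature mean with
10 prior degrees of freedom (empirical-Bayes moderation in the limma style —
with 3 replicates per group an unmoderated test has almost no power, and
log-count variances are highly exchangeable across features). P-values are
BH-adjusted across features within each timepoint. An input port accepts an
external DE table (feature, timepoint, lfc, padj) so a negative-binomial
engine's output can drive the identical downstream logic.

A feature is DE when some timepoint has padj < 0.05 and |log₂FC| > 1. The
two-sided reading is the default (down-regulated clusters plainly exist in
time-course data); a one-sided mode is available. Fold-change profiles over
the four timepoints (1, 3, 6, 12 h) are clustered with Ward linkage on
Euclidean distance; when k is unset it is chosen by maximum silhouette over
k ∈ 2..8. Clusters are named by rule from their mean profile (up-back, up,
down, down-back, flat, mixed). Each (DETE, DEG) co-localisation — TE inside
the gene unit or its 2 kb flanks — yields one pair; a TE near several genes
yields several pairs, never a dropped one. A pair is concordant when both
members fall in the same joint cluster; the headline quantity is the
concordant fraction.

## Long-read classification

A read's biological 5′ position is strand-aware (rightmost aligned base on
the − strand). A sense-overlapping read "initiates within" a locus unless
its 5′ position lies upstream of the locus's 5′ boundary in locus
orientation; reads starting downstream of the 3′ boundary count as
within-class internal starts. Per-locus categories: All_within (de novo
transcription), All_upstream (read-through), Mix. For loci with read-through,
each upstream-initiating read's 5′ position is looked up in the compartment
map (exon → exonic, intron → intronic, else no_gene) and the locus label is
the majority, ties resolving exonic > intronic > no_gene.

Alignment ends are classified per read end (read orientation): *clipped*
when the soft-clip is ≥ `clip_min` (20 bp, above typical adapter/error
residue), else *external* when the alignment passes the corresponding locus
boundary, else *internal*.

Breadth of coverage is |union of (blocks ∩ feature)| / |feature| over the
superfamily-specific autonomy feature (INT / ORF / whole element). A read
evidences a full-length transcript when its length is at least the feature
length and its mapped fraction (M/=/X bases over read length) is ≥ 0.9 —
the chosen quantification of "almost fully mapped". The autonomy screen
reports structurally intact loci with breadth > 0.9, each with its (possibly
empty) list of full-length reads: broad coverage without one contiguous
qualifying read is exactly the "transcribed, but no autonomous transcript"
outcome. Multi-mapping long reads are retained and flagged; each placement
contributes to breadth only at its placed locus.

## Splicing and productivity

Isoforms are exon-block models with the spliced sequence derived from the
genome, strand-aware. Against the gene's reference isoform (the longest
transcript): IR = a reference intron fully exonic in the isoform; ES = a
reference exon absent while an isoform intron spans it (such spanning
introns are not additionally reported as Alt events); Alt3/Alt5 = a junction
sharing one edge with a reference junction and shifted at the other, typed
by which edge moved in transcript orientation, with the shift interval as
the feature. TE overlap is recorded at ≥ 1 bp intersection.

Productivity assumes translation from the first ATG of the spliced
sequence: no ATG → NGO; no in-frame stop → NST; an in-frame stop ≥ 50 nt
upstream of the final exon–exon junction → PTC (the standard NMD
convention; both constants configurable); otherwise PRO. For PTC isoforms
with a TE-overlapping retained intron, the TE's exonic footprint is
projected into transcript coordinates and the stop codon placed within /
before / after it; distances are transcript-coordinate gaps (genomic
distances would be inflated by any spliced-out sequence between the stop
and the TE).

## Synthetic data: what it emulates and what it does not

The generator lays genes on a regular grid (alternating strand) and carves
TE loci into quota-controlled compartments; intact LTR loci get
LTR5/INT/LTR3 sub-features with the 3′ LTR mutated from the 5′ at the
planted divergence (transition:transversion 2:1), intact TIR loci get a
central ORF. Alignments are *authored*, not aligned: multiplicity (NH),
mate structure, soft-clips and spliced blocks are written directly, which
isolates the pipeline's logic from aligner behaviour. Count matrices are
negative-binomial (dispersion 0.1, 3 replicates, 4 timepoints) around
planted fold-change archetypes (up-back, up, down, flat; the early-response
"up-back" mirrors a wounding-style transient), with co-localised TE–gene
pairs sharing archetypes at a planted rate and a 4:1 flat background
anchoring the normalisation. Everything is deterministic under (plan, seed);
the manifest records every planted truth.

Default problem sizes — 2 × 250 kb chromosomes, 24 genes, ~50 TE loci,
~10³ short reads, tens of long reads, 30 TE–gene pairs over 5–8 seeds —
are chosen so the full suite runs in minutes on one CPU while every
statistical check retains adequate resolution at its stated tolerance.

What passing on synthetic data does **not** show: robustness to aligner
artefacts (soft-clip conventions, split mappings), sequencing error,
polymorphism between the sample and the reference, overlapping/nested TE
annotations at real-genome density, or NB dispersion trends across
expression strata. Results on real data depend on annotation quality in
ways the quota-based generator cannot probe.

## Numerical and degenerate-input choices

- All count/depth thresholds are strict; boundary cases (10 reads, depth
  5.0) fail by construction.
- Coverage depth is exact per-base accounting (numpy arrays per locus), not
  an approximation.
- KDE peak: first grid argmax → smallest time on ties; < 10 values raises.
- Saturated LTR pairs are excluded, never clamped to a maximum age.
- Genes missing from the expression table are treated as not expressed and
  logged.
- `chisq_location_bias` renormalises expected proportions that do not sum
  to 1 and refuses zero-expected categories.
- A single-exon isoform can never be PTC (no junction), so an in-frame stop
  there is PRO.

## Known limitations

- The DE stand-in is not a negative-binomial GLM; dispersion shrinkage,
  independent filtering and Wald/LRT machinery are out of scope. Use the
  external-table port when exact NB results matter.
- Integrity ignores internal deletions by design; a locus with a large
  internal gap but full-length span still counts as full-length.
- The dangler orientation rule assumes standard FR paired-end geometry.
- Peak times inherit the uncertainty of r; only ratios of peak times are
  rate-free.
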