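# Methods

## Overview

`polyfusion` implements a bottom-up analysis of polymorphic gene fusions:
instead of calling structural variants (SVs) genome-wide and asking which
ones might disturb genes, it starts from transcript evidence — chimeric RNAs
observed in RNA-seq — and works back to the DNA rearrangement.  The
discriminating observation is distributional: a chimera caused by a
segregating DNA variant is present in a *subset of individuals* but, within
each carrier, across *many tissues and most samples*; a chimera arising
from sporadic intergenic splicing is either ubiquitous across the cohort or
sporadic within individuals.

The package has five analysis stages (catalog filtering, breakpoint
genotyping, SV evidence, population genetics, phenotype association) and a
synthetic-cohort generator that plants known variants so every stage can be
validated against ground truth.

## Synthetic cohort generator

The generator emulates a multi-tissue donor biobank over a toy locus:

* **Reference and locus.**  A random 50-kb contig carrying two genes in
  opposing orientations.  The default planted rearrangement is an
  inversion of 4824 bp with an immediately adjacent deletion of 3228 bp —
  the geometry and sizes of the pseudogene–gene complex rearrangement that
  motivates the package.  Single deletions, tandem duplications and
  inversions of comparable size are available for the type-recovery
  experiments.  Coordinates are 0-based half-open everywhere internally;
  1-based coordinates appear only in SAM emission.
* **Genotypes.**  Individuals are drawn per population as
  Binomial(2, allele frequency) — exact Hardy–Weinberg sampling.
* **Haplotypes and liftover.**  Applying an SV yields the alternate allele
  sequence together with a piecewise-linear haplotype→reference map and one
  junction record (±70 bp of context) per novel adjacency.  Junction
  sequences occur verbatim on the alternate haplotype and nowhere on the
  reference (a property the test suite asserts).
* **Reads.**  Paired-end fragments are drawn per allele in proportion to
  genotype dosage; insert sizes are Normal(350, 50) truncated below at the
  read length; pairs are FR-oriented on their haplotype.  Truth alignments
  are computed through the liftover, so reads crossing a novel adjacency
  become discordant or split in reference space without running an aligner.
  Sequencing error is uniform substitution only (default 0.1%); no indel
  errors, so approximate-matching behaviour stays interpretable.  Default
  read length 100 bp, coverage 30×.
* **Chimera tables.**  Carrier samples express a linked chimera with
  per-sample penetrance 0.9 (the carrier penetrance of the fusion is not
  reported anywhere we know of; 0.9 is a deliberate, configurable guess).
  All samples additionally express it at a genotype-independent background
  rate, default 0.005, standing in for trans-splicing.  Confidence scores
  and annotated-transcript identities are uniform draws within configurable
  ranges.
* **Phenotypes.**  Clinical codes are Bernoulli draws from a logistic model
  `logit(p) = logit(prevalence) + ln(OR)·g`, with `g` coded dominant or
  additive per planted effect.  Covariates: age ~ Uniform(20, 80) years,
  sex ~ Bernoulli(0.5), five ancestry PCs standard normal with a
  population-specific shift on PC1.

What the generator does **not** emulate: base-quality structure, PCR
duplicates, indel error, GC bias, mappability structure of a real genome,
linkage between variants, or realistic phenotype correlation structure.
Tests passing on this cohort demonstrate the pipeline's logic and
statistical calibration, not its performance on real short-read data.

## Catalog filtering

* **Confidence filter**: keep predictions with score ≥ 0.6, defined
  junction coordinates, and ≤ 90% identity to annotated transcripts.
  Both inequalities are phrased as removals (score < 0.6, identity
  > 90%), so retention is ≥ / ≤ at the boundaries.
* **Junction classes**: each junction side is End-of-exon (E) if it lies
  within ±2 bp of the strand-appropriate exon edge (donor side against
  exon 3′ edges, acceptor side against 5′ edges), else Middle-of-exon (M).
* **Polymorphic filter**: a chimera is selected when seen in fewer than 250
  unique individuals and, over expressing individuals, present in more than
  5 unique tissues and more than 2/3 of each individual's samples.  The
  criterion wording ("within each individual") is ambiguous between a
  per-individual and a mean-over-individuals reading; the default applies the thresholds to the
  per-individual means (`aggregation="mean"`), matching the way such
  screens are usually plotted, with `per_individual_all` selectable.  All
  thresholds are strict inequalities; the 66% threshold is exactly 2/3 by
  default and configurable.  Mean aggregation is fragile to background
  expressors: genotype-independent singleton expressors drag the mean
  sample fraction down, which is worth knowing when tuning the background
  rate.
* **Frame prediction** requires CDS on both sides of the junction:
  IN_FRAME iff the 5′ partner's cumulative CDS length to the junction is
  congruent modulo 3 with the 3′ partner's CDS phase at its junction;
  NON_CODING when the 5′ junction precedes the CDS or the 3′ junction
  leaves no CDS downstream.  Mid-exon phases are computed from genomic CDS
  intervals, not transcript models — adequate for the toy annotation, a
  simplification for real GTF complexity.

## Breakpoint genotyping

Per sample: quality-filter reads (mean base quality ≥ Q20, ≤ 10% N);
approximate-match each 70-bp query against both strands of every read;
re-map matching reads; count true positives per query; apply a boolean
presence rule.

* **Approximate matching** is substring (infix) Levenshtein search, exact
  by default (`max_edits = 0`, matching the default behaviour of the
  original fuzzy-matching tool) and tolerant up to a configurable k.  The
  implementation uses the Myers bit-parallel algorithm via `edlib`; an
  exhaustive dynamic-programming oracle, written independently, verifies it
  exactly over randomized instances in the test suite and acceptance
  script.
* **Re-mapping validation** discards fuzzy hits that originate elsewhere in
  the genome (repeats, paralogs — the pseudogene/parent-gene problem).  A
  k-mer (k = 11) seeded candidate search followed by an edit-distance
  optimal alignment path, scored match +1 / mismatch −1 / gap −2, identity
  = matches / alignment columns.  Alignments with score ≥ 90 and identity
  ≥ 0.90, within 1% of the best retained score, define the read's loci:
  all inside the 100-kb target window → TRUE_POSITIVE; none → FALSE_POSITIVE;
  mixed → UNCERTAIN; nothing retained → dropped from evidence.  Only
  true-positive counts feed the genotype rule.
  A breakpoint-spanning read has no full-length colinear reference
  alignment (a 100-bp read carrying a centred 70-bp junction query has at
  most ~65 contiguous reference bases, below the score threshold), so the
  re-mapping target also includes the variant junction context sequences,
  flagged as part of the target locus.  This keeps the step's purpose —
  off-target screening — while retaining true junction evidence.
* **Rule engine.**  Calls are boolean expressions over query presence
  (count ≥ `min_reads_present`, default 1), e.g. the complex-rearrangement
  rule `CTRL & JUNCTION & !DEL_INTERNAL`.  Note that
  this verbatim rule cannot call heterozygous carriers positive — a
  heterozygote retains the reference allele, so the deleted-region query is
  present.  The rule engine reproduces whatever rule it is given; the
  recovery experiments use the detection rule `CTRL & JUNCTION_1`, which
  measures carrier status correctly under Hardy–Weinberg sampling.
  A sample with zero evidence reads across all queries is NO_CALL.

## SV evidence from discordant pairs

Pair orientation is derived from reference-space mate strands ordered left
to right: FR (normal), RF (outward-facing, the tandem-duplication
signature), FF/RR (the inversion signatures; "left–left"/"right–right" in
genome-browser terms).  A pair is concordant iff FR with insert within 3
standard deviations of the insert model; discordant pairs are clustered per
orientation class with a proximity gap of one insert mean.

Classification rules (all supporting clusters ≥ 3 pairs):

| call | signature | coverage condition |
|---|---|---|
| INV | FF and RR clusters | — |
| COMPLEX_INV_DEL | FF and RR clusters | depleted run (< 0.7× flanks) starting within 1 kb of the downstream inversion breakpoint, ≥ 500 bp long |
| DUP | RF cluster | ratio > 1.3 inside the implied interval |
| DEL | long-insert FR cluster | ratio < 0.7 inside the implied interval |

The gain/loss thresholds (1.3 / 0.7) and minimum support (3 pairs) are this
package's quantitative stand-ins for what is judged by eye on read
pile-ups; they sit safely between the heterozygous expectations (1.5 / 0.5)
and coverage noise at 30×.  Flank windows for the coverage ratio equal the
candidate interval length.  Split reads refine breakpoints when present but
are not required.  Breakpoint estimates are cluster medians; localization
error is bounded by the insert mean in the test suite.

Matching a call to a chimera's gene pair (DIRECT_EVIDENCE) requires an
intrachromosomal pair, breakpoints within 100 kb of both parental genes,
and geometry capable of a transcribable 5′→3′ adjacency: deletions and
duplications fuse same-strand neighbours, inversions (and inversion+deletion
complexes) re-orient one partner of an opposite-strand pair.
Interchromosomal pairs are reported NO_EVIDENCE by construction.

## Population genetics

Allele frequency is `(n1 + 2·n2) / 2N`.  The Hardy–Weinberg test is a 1-df
chi-square against `(p²N, 2pqN, q²N)` without continuity correction, with
the exact conditional test (sum of heterozygote-count probabilities no more
likely than observed) selectable for small expected counts.  Monomorphic
populations are in equilibrium by convention (χ² = 0, p = 1).  Detection
summaries report `100·detected/total` rounded half-up to one decimal,
matching printed-table formatting.

## Association

Codes enter a screen with ≥ 20 total instances and ≥ 1 instance among
carriers (both inclusive).  The dominant model is a maximum-likelihood
logistic fit (Newton/IRLS, tolerance 1e-8, max 100 iterations) of the
binary carrier indicator with covariates; the additive model is an
ordinary-least-squares fit on allele count — linear regression on a binary
outcome is unusual but is the conventional fast PheWAS configuration this
mirrors, and `additive_logistic` is provided for the orthodox alternative.
P-values are Wald tests on the genotype coefficient (standard
PheWAS-package behaviour), OR = exp(β), Bonferroni over the tested set.
Perfect separation is flagged and the Wald p withheld rather than switching
to penalized regression, which would silently change the estimand at small
carrier counts.  Degenerate or collinear covariate columns are dropped with
a warning.  Repeat samples per donor are collapsed to unique donors before
modelling.

## Numerical and design notes

* Every generator is a pure function of its configuration and seed; the
  pipeline is byte-deterministic under a fixed seed.
* Experiment problem sizes: recovery experiments run on 50-kb contigs at
  30× coverage (200-sample genotyping cohort; 100 replicates per SV type;
  100 polymorphic-filter replicates with 300 donors × 30 tissues; 2000 null
  populations for HWE calibration; 600 codes × 1000 individuals for the
  null PheWAS).  These sizes give binomial standard errors small enough for
  the stated bounds while keeping the whole suite fast on one CPU.
* The genotyping recovery cohort uses allele frequency 0.2 (≈ 36%
  carriers), chosen so both carrier classes are well represented in 200
  samples.
* The polymorphic-filter recovery experiment plants one polymorphic chimera
  (10% carriers, penetrance 0.9) against 50 ubiquitous decoys with zero
  trans-splicing background — the mean-aggregation rule is exactly
  diluted below its threshold by background singletons otherwise (see
  above).
* Ties in fuzzy-match strand assignment prefer the plus strand; re-mapper
  loci within twice the seed slack are deduplicated keeping the best score.

## Known limitations

* The re-mapper is a locus-scale tool (the 100-kb window plus junction
  contexts), not a genome-scale aligner; genome-wide decoy screening is
  only as good as the contigs given to it.
* SV calling covers DEL / DUP / INV / inversion+deletion complexes;
  insertions, mobile elements and interchromosomal events are out of scope.
* The additive "linear" model inherits the heteroscedasticity of linear
  probability models; use `additive_logistic` when calibration matters.
* Junction/frame annotation works from genomic exon and CDS intervals, not
  full transcript models.
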