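# Methods

## The problem

Amplicon deep sequencing around a CRISPR/Cas9 target is the standard way
to estimate editing efficiency: align every read to the reference
amplicon and count the fraction carrying an insertion, deletion or
substitution inside a quantification window centred on the cut site.  We
call the resulting statistic the *alleged* editing efficiency (AEE)
because, at this stage, nothing distinguishes a Cas9 repair product from
pre-existing genetic variation that happens to fall inside the window.
In organisms without well-curated reference genomes — the motivating
setting is a non-model crustacean with abundant polymorphism, divergent
sex-chromosome haplotypes and a repeat-rich genome — this confusion is
not a corner case but a routine hazard.

The package implements the full diagnostic workflow around that hazard:

1. **Dual-window AEE.** Each sample is quantified twice, in a narrow
   window (w = 2 nt, one base each side of the blunt cut) and a wide
   window (w = 20 nt).  True NHEJ indels are anchored at the cut and
   register in both; flanking variation registers only in the wide one.
   The screening statistic is Δ = 100·(AEE₂₀ − AEE₂) percentage points.
2. **Control-derived threshold.** Δ is compared against a threshold
   derived from the positive control: the largest discrepancy observed
   there, rounded to whole percentage points (10 pp under the default
   study conditions).  Loci with Δ ≤ threshold are "concordant"; the
   boundary belongs to the concordant group.
3. **Artifact classification.** Discordant loci are interpreted by
   comparing allele tables from an sgRNA-free control with the treated
   sample (rules below).
4. **GUIDE-seq-style off-target calling** from dsODN-tagged reads on a
   small genome.
5. **Expression–efficiency association** by Spearman rank correlation.

## Alignment and event model

Reads are aligned end-to-end (global Needleman–Wunsch with affine gaps;
Biopython's `PairwiseAligner` provides the dynamic programming) under
match +2, mismatch −1, gap open −6, gap extend −1, where a gap of length
L costs 6 + L.  Reads below 60% identity (matches over alignment
columns) are discarded rather than classified; the floor rejects junk
while keeping NHEJ alleles with multi-nucleotide lesions alignable.  All
scoring parameters are exposed in configuration.  The alignment path is
decomposed into atomic events: per-base substitutions, maximal deletion
runs over reference intervals, and insertion runs anchored at inter-base
coordinates.  Coordinates are 0-based, half-open, with the cut site an
inter-base coordinate 17 nt from the protospacer 5′ end (the canonical
SpCas9 blunt cut, 3 bp 5′ of the NGG PAM).

**Indel placement ambiguity.** Within repeated sequence, the same read
admits several score-equivalent indel placements.  Events are *reported*
at their leftmost placement (the usual variant-normalisation convention,
which makes allele collapsing and rendering deterministic).  For the
window membership test, however, an indel counts as in-window if *any*
placement in its equivalence interval (leftmost through rightmost)
touches the window.  Judging only the leftmost placement would
systematically drop genuine cut-site deletions whose left flank is a
homopolymer — on random sequence roughly a tenth of NHEJ deletions slide
out of a 2-nt window that way — biasing AEE₂ downward by several points.
With the equivalence-range rule the estimator is unbiased up to
sequencing error, which the recovery tests confirm.  Substitutions have
no placement ambiguity; substitutions involving N are not counted as
modifications.

Window semantics: a window of width w is the half-open interval
[cut − w/2, cut + w/2), clipped to the amplicon.  Deletions count on
interval overlap, insertions when an equivalent anchor lies strictly
inside, substitutions when their position is inside.  Because the 2-nt
window is nested in the 20-nt window, AEE₂ ≤ AEE₂₀ always; the code
asserts it on every run.

## Allele tables

Aligned reads are collapsed by their rendered aligned sequence over a
±20 nt span around the cut (deletions drawn as `-`, insertions as
lowercase runs in parentheses).  Each record carries count, frequency
relative to aligned reads (frequencies sum to 1), the events inside the
span, and modified flags for both windows; ordering is count-descending
then lexicographic, so tables are deterministic.

## Classification rules

Parameters (all in configuration): noise floor 2% of aligned reads
(separates sequencing error from variation signal), major-allele floor
10%, control/treated frequency-match tolerance 10 pp.  Rules apply in
order to the sgRNA-free control table; the first match wins, and the
result is invariant to allele row order:

1. **NO_ARTIFACT** — control Δ ≤ threshold and control AEE₂ ≤ noise
   floor: nothing to explain.
2. **REPEAT** — control AEE₂ above the noise floor ("editing" without
   sgRNA inside the narrow window), or at least two indel-bearing
   modified allele families in the control.  Repeat evidence precedes
   the homolog rule because narrow-window false positives are its
   distinguishing signal.
3. **DIVERGENT_HOMOLOG** — exactly one substitution-only control allele
   above the major-allele floor, mirrored in the treated table at the
   same spanning sequence within the frequency tolerance.  Amplicon
   data cannot show *which* chromosome the second haplotype lives on
   (sex chromosome versus autosomal divergence); the label asserts only
   the allele pattern.
4. **SNP** — all modified control alleles substitution-only, each below
   the major-allele floor, collectively above the noise floor: a cloud
   of population polymorphisms.
5. **UNCLASSIFIED** otherwise.

A genuine ambiguity: a *single* SNP at high carrier frequency produces
exactly the divergent-homolog pattern (one major substitution-only
allele present in both samples) and is labelled as such — from amplicon
data alone the two are the same observation.  The SNP label, per rule 4,
describes the multi-allele low-frequency cloud.

**Corrected efficiency** removes from the treated modified fraction any
allele whose spanning sequence also occurs in the control above the
noise floor; it can never exceed the uncorrected AEE.  This is a
pragmatic control-subtraction, not an attempt to deconvolve editing of
variant haplotypes.

## Statistics

AEE proportions are arcsine-transformed (arcsin √p) before testing.
Homogeneity of variance uses the mean-centred Levene test
(`scipy.stats.levene`).  The window comparison is a repeated-measures
ANOVA in its two-level within-subject special case — each locus is
measured at both windows — which is identical to the squared paired-t
statistic with p from F(1, n−1); the tests assert that identity to
1e-9 relative tolerance.  The grouping factor (concordant/discordant) is
handled by running the paired test separately per group; a two-factor
mixed design would also be defensible but adds nothing at two levels.

Spearman's rho uses average ranks for ties and the t approximation with
n − 2 df for the p-value (a seeded permutation alternative is provided
for small n); it is checked against an O(n²) brute-force rank oracle and
against `scipy.stats.spearmanr`.

Expression normalisation is median-of-ratios size factors followed by
log2(x + 1) and a replicate mean.  This is a deliberate stand-in for the
regularised-log transform: rank correlation downstream is insensitive to
monotone differences between the two, and the shrinkage behaviour of
rlog matters only for genes near zero counts.  Size factors are defined
up to a common scale; we fix it by rescaling to median 1, so identical
replicates get factor 1 and a doubled column reads exactly 2.  The exact
scale-equivariance statement is therefore about size-factor *ratios*
(scaling one replicate by c scales its factor by c relative to every
other), because the per-gene geometric-mean reference itself moves when
a column is rescaled.

## GUIDE-seq-style off-target calling

A read is dsODN-tagged when the 34-nt tag occurs in it, in either
orientation, within a 1-mismatch budget; the genomic flank 5′ of the tag
junction (minimum 20 nt) is mapped back to the genome with an exact
k-mer seed index (k = 12, mismatch budget + 1 disjoint seeds, Hamming
verification — equivalent to an exhaustive both-strand scan at these
genome sizes, which the tests assert).  Junctions within 10 nt on a
contig merge into an integration site; sites need ≥ 2 distinct reads.
Each site is scored by the best ungapped protospacer+PAM placement
within ±25 nt, preferring NGG placements, minimising protospacer
mismatches, breaking ties toward the junction; a site is on-target iff
it has zero mismatches and sits at the designed cut.  No UMI
consolidation is performed — the simulator emits unique molecules — so
on real libraries with PCR duplicates the distinct-read counts would
overstate molecule counts; this is a documented limitation, not a claim
about real chemistry.  Because the natural denominator of an off-target
read fraction is ambiguous, reports emit the fraction of *total* reads
and of *tagged* reads side by side.

## The synthetic-data generator

The generator emulates the read structure the analysis assumes, not a
sequencer: one merged read spans the whole amplicon (the analysis unit
after paired-end merging), with fixed quality.  Per read, a template of
origin is drawn — primary, one optional divergent homolog
(substitution-only divergence, equal length), or co-amplified paralog
templates with mixture weights — then population SNPs are applied to
primary reads by carrier frequency, one NHEJ indel is applied to primary
reads with probability e (the true editing fraction), and uniform
substitution-only sequencing error is layered on top.  Each read gets a
ground-truth record (origin, edited flag, events).

Choices that matter, with defaults and reasons:

- **Indel spectrum**: 80% deletions with geometric(0.5) lengths capped
  at 10 nt, insertions uniform 1–3 nt — short, deletion-dominated NHEJ
  outcomes that produce realistic allele tables.  Deletions are placed
  covering the cut; insertions anchor at it.
- **Editing applies to primary-template reads only.**  Paralogs
  originate elsewhere in the genome; the divergent homolog is modelled
  as uncut, on the grounds that divergence near the target disrupts
  guide binding — consistent with a control-sample haplotype persisting
  at a matching frequency in the treated sample.
- **SNP offsets exclude the 2-nt window** (offsets −1 and 0 are
  rejected): the scenario models flanking variation by construction.
- **Error model**: uniform per-base substitution (default 0.001); no
  quality scores, no PCR chimeras, no paired-end artefacts.  AEE uses
  sequence identity only, so qualities would be dead weight.
- **GUIDE-seq simulation**: blunt dsODN integration at the cut; reads
  carry 25–60 nt of upstream flank, the tag, and downstream flank to a
  fixed read length, half reverse-complemented; planted off-target
  footprints keep an NGG PAM and confine mismatches to the protospacer.
- **Expression/editing tables**: a Gaussian copula couples latent
  expression with editing efficiency at a requested Spearman correlation
  (ρ_Pearson = 2 sin(πρ_s/6)); counts are negative-binomial
  (dispersion 0.1) over six replicates, efficiencies run through a
  right-skewed beta quantile, hence deliberately non-normal.

What passing tests therefore show: the estimator, threshold logic,
classifier, off-target caller and statistics recover planted truth under
the stated read structure.  What they do not show: robustness to real
library artefacts (quality decay, chimeric reads, UMI structure,
alignment to a wrong reference), which the generator does not emulate.

## Study conditions and problem sizes

The pre-configured studies in `ampedit.studies` fix the simulation
conditions used by the analysis scripts, the tests and the acceptance
script: editing-fraction recovery at n = 10,000 reads and e = 0.41;
100 random mixed scenarios for window nesting; the three variation cases
at 6,000 reads each (SNP carrier 0.49 at offset −8; homolog at 21.6%;
repeat families at weights 0.106/0.796); the positive-control surrogate
at 50,000 error-free reads with e = 0.41 plus a 17.15% flanking carrier
(so the wide-window surplus is (1 − e)·0.1715 ≈ 10.1 pp); a 224-locus
cohort with 23% variation-bearing loci at 150 reads each; 200 classifier
loci (50 per class) at 300 reads per sample; 20 GUIDE-seq simulations on
20-kb genomes plus one 65,517-read deep library; and 50-gene expression
cohorts with a 30-seed recovery mean.  These sizes keep binomial noise
well inside the tolerances being tested while the full suite runs in
well under a minute per study on one core.

## Degenerate inputs and numerical conventions

Zero aligned reads, empty control lists, a zero-discrepancy threshold,
all-zero count tables, constant rank vectors and zero within-group
deviations are all errors with specific messages rather than NaNs.
All-zero paired differences in the repeated-measures test return
F = 0, p = 1 (a defined no-effect answer).  Threshold rounding is
half-up to whole percentage points.  Every stochastic routine takes an
explicit integer seed; identical seeds give byte-identical FASTA/FASTQ
output.

## Known limitations

- Substitutions inside the window count as modifications (the AEE
  definition includes them), so sequencing error contributes ~w·ε to
  AEE at error rate ε; the wide window inherits a ~2-pp ceiling of
  error inflation at ε = 0.001 before any variation is present.
- The classifier's labels describe allele patterns, not genomic loci;
  it cannot place a divergent haplotype on a chromosome, count repeat
  copies, or distinguish a single high-frequency SNP from a divergent
  homolog.
- HDR alleles, base-editing outcomes and quality-aware calling are out
  of scope; paired-end merging is assumed done upstream.
- The off-target caller is desk-scale by design: exact k-mer seeding
  over megabase-scale genomes is fine, but it is not a replacement for
  a production GUIDE-seq pipeline (no demultiplexing, no UMIs, no
  adapter chemistry).
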