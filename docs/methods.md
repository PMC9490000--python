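# Methods

This note documents the models, parameter choices and numerical conventions
behind `cnvpop`, and what the synthetic benchmarks do and do not establish.

## Depth normalization and the window grid

Chromosomes are tiled with fixed non-overlapping windows (default 800 bp,
0-based half-open); a trailing partial window is dropped, and chromosomes
shorter than one window contribute none. Raw per-window depth is divided by
each individual's **median** window depth rather than the mean: the median
is robust to the CNV windows themselves, so the diploid bulk of the genome
defines the baseline even in CNV-rich samples. The per-individual STDEV
entering the statistical calling criterion is the plain (ddof = 0) standard
deviation of the normalized column, computed after normalization. A
per-chromosome normalization mode exists for sex-chromosome work; by
default all chromosomes share the individual's global median. No GC or
mappability correction is applied; the depth-TSV contract is the hook point
— any corrected depth matrix can be supplied in place of raw counts.
Windows whose across-individual mean raw depth falls below 10% of the grand
mean (configurable) are excluded from candidacy as unmappable/gap-like.

## Calling thresholds

The two-criterion rule is conjunctive by design. The statistical criterion
(|RD − 1| > 2·STDEV) adapts to each sample's noise; the empirical cutoffs
(0.65 / 1.35) sit between the diploid expectation 1.0 and the heterozygous
expectations 0.5 / 1.5 and stop low-noise samples from calling trivial
fluctuations. "Carrier frequency" is carriers/individuals (read-depth data
has no phased alleles to count); homozygous carriers are recognized at
RD < 0.25 (between copy numbers 0 and 1) and RD > 1.75 (between 3 and 4).
Candidate filtering runs per analysis group — each population separately
and the pooled panel — because a variant common in one population can fall
under the frequency floor when diluted across the whole panel.

Adjacent-window and call→CNVR merging both use the Pearson t-test
two-sided p-value with df = n − 2; ties at p = α do not merge, and a
constant RD vector leaves the correlation undefined, which never merges
(logged). The CNVR gap rule takes "distance" as the gap between the left
call's end and the right call's start (0 when touching) and "combined
length" as the sum of the two call lengths. Merging proceeds left-to-right
per chromosome and iterates to a fixpoint, so the result is scan-order
independent; the merged region's RD vector is recomputed over the full
span (including bridged gap windows) before further merging decisions.

Cross-population CNVR identity uses ≥ 1 bp overlap. A reciprocal-overlap
fraction is deliberately not imposed by default: at these region sizes
(~1–8 kb) any overlap on a shared window grid is strong evidence of the
same event, and the looser rule keeps Venn counts conservative about
"unique" labels.

## Annotation and enrichment

Genic context uses exon > intron > intergenic precedence on merged exon
intervals; strand is ignored (CNVs are unstranded). Gene assignment keeps a
gene when the overlap covers at least 50% of the *shorter* of gene and
region — the denominator the qualitative rule "completely or partially
overlapping" implies, since complete containment of either feature then
always qualifies. Enrichment is the hypergeometric upper tail
P(X ≥ k | N, K, n) with Benjamini–Hochberg FDR across all tested terms; the
background defaults to all genes in the annotation and is configurable.
QTL and cross-study intersections use plain ≥ 1 bp interval overlap with
half-open coordinates on both sides.

## Vst

All three variance terms use the unbiased sample variance (divisor n − 1),
applied exactly as the size-weighted decomposition requires. This choice is
fixed and documented because it changes numeric values: the worked example
pop1 = [1,1,1,1], pop2 = [1,1,3,3] gives Vst = 2/9 ≈ 0.2222 under n − 1 but
1/3 under divisor n. The per-individual value for a region is its mean
normalized RD over the grid windows the region spans (a log2 option exists
for comparison with array-era log-R-ratio conventions). Records with zero
pooled variance are flagged undefined and excluded from rankings and means;
negative Vst values are reported as computed, not clamped. "Divergent"
selection is rank-based — both the top five regions and the top 1% are
emitted — since no significance test is defined for the statistic here;
permutation testing is a documented extension, not implemented.

## qPCR

Copy number = reference copy number (2) × 2^−ΔΔCt, assuming amplification
efficiency 2.0. Technical replicates are mean-averaged on the Ct scale
before any delta is formed. Concordance classification uses integer
midpoints 1.5 / 2.5 between copy numbers 1–2 and 2–3. The calibrator sample
must be named explicitly.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the study design the pipeline assumes: three
populations × 8 individuals, ~7× mean depth, 800 bp windows, an L-shaped
CNV length distribution (truncated geometric over 1–10 windows, i.e.
0.8–8 kb), duplications three times as frequent as deletions
(gain fraction 0.75), CNVRs shared by all populations or private to one
(default 30 shared + 10 private per population), and a few divergent
regions fixed in one population and absent elsewhere. Carrier copy numbers
are drawn per carrier (loss: 1, occasionally 0; gain: 3, occasionally 4);
carriers of a *fixed* divergent allele are homozygous (copy number 4 for a
duplication, 0 for a deletion), which is what fixation implies. Planted
regions snap to the window grid and are kept at least one window apart, so
truth comparisons are exact.

Depth noise models the window's total base coverage as a Poisson count
with expectation mean_depth × window × copy_number/2 ("poisson", the
default and the clean case), as a gamma-Poisson mixture with dispersion
0.1 ("negative-binomial", matching the overdispersion of real short-read
coverage), or as the exact expectation ("none", for exact tests). The
Poisson mode deliberately understates window-level variance relative to
real data — reads correlate adjacent bases, and mappability/GC structure
adds systematic wiggle — so passing benchmarks in Poisson mode demonstrate
the *logic* of the pipeline (thresholds, filters, merging, accounting,
Vst), not its error rates on real genomes. The negative-binomial mode is
the stress setting: under strong overdispersion the adaptive statistical
criterion widens with STDEV and sensitivity for heterozygous events drops,
which mirrors how real low-coverage panels behave.

## Benchmark problem sizes

The recovery benchmark calls and merges a 24-individual panel over a ~9,000
window genome (four chromosomes of 2.4/1.8/1.2/0.6 Mb) with planted CNVRs
of ≥ 4 windows at carrier frequency ≥ 0.25, then scores region-level
sensitivity and precision against truth at ≥ 1 bp overlap. Null specificity
uses a 10,000-window, 24-individual panel with nothing planted. Vst
recovery runs 100 replicates of an 8-vs-8 fixed-difference duplication
among ~15 null regions. These sizes keep the full suite and the acceptance
script in the seconds-to-minutes range on one CPU while leaving every
statistical filter with realistic work to do.

## Known limitations

- No integer copy-number genotyping; states are GAIN/LOSS/NORMAL with mean
  RD. Absolute copy estimates come only from the qPCR module.
- Depth must be precomputed per window (TSV contract); alignment, duplicate
  marking and QC are upstream of this package.
- Enrichment is over user-supplied gene→term maps; no live ontology access
  and no EASE-style modified Fisher score.
- The ≥ 1 bp cross-population identity rule can chain distinct events
  through a long bridging region on dense CNV landscapes; the exposed
  reciprocal-overlap option is the sensitivity check for that.
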