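# Methods

## Model

`msirepeat` classifies a tumour sample as MSI-H or MSS from amplicon
sequencing of N short mononucleotide repeats (MNRs, 7–12 bp poly-A or
poly-C), each with at least one common SNP within 30 bp. Per marker the
observation is reduced to a pair of indicators O_i = (D_i, B_i):

* D_i = 1 iff the fraction of concordant read pairs carrying any
  deletion exceeds the marker threshold t_i. Deletions of every size
  are pooled; insertions count toward the denominator only.
* B_i = 1 iff, at the heterozygous flanking SNP with the lowest
  two-sided Fisher p (ties broken by panel order), the association
  between deletion status and allele is significant at alpha = 0.05.

The score is naive Bayes on these indicators:

S = log10 p(MSI)/p(MSS) + Σ_i log10 [p(D_i|MSI)/p(D_i|MSS)] +
    Σ_{i: D_i=1, bias assessable} log10 [p(B_i|D_i=1,MSI)/p(B_i|D_i=1,MSS)]

Call = MSI-H iff S > 0. The model's assumptions: markers mutate
independently given MMR status; the bias indicator is exchangeable
across samples given D; priors p(MSI) = 0.15 / p(MSS) = 0.85 reflect
the approximate MMR-deficiency rate among colorectal tumours and are
configurable per training run.

When the bias cannot be computed — D_i = 0 (insufficient evidence for a
repeat mutation, so allele distribution is not meaningful), no
heterozygous flanking SNP, or no eligible training samples in one class
— the bias factor is omitted, i.e. set to 1, so missing data never
favours either class. The factor is skipped for *all* samples when
either class lacks eligible training samples, to avoid asymmetric
evidence from an unestimable quantity.

## Training

* t_i is the nearest-rank 95% upper quantile of the deletion fractions
  of usable MSS training samples: sorted ascending, t = x_(k) with
  k = ceil(0.95 n). At most n − k samples lie strictly above. This is
  an explicit order-statistic definition; on small cohorts the realised
  coverage is k/n, not exactly 95%.
* p(D=1|class) uses exact exceedance counts; p(B=1|D=1,class) uses the
  subset of above-threshold samples heterozygous at ≥ 1 flanking SNP.
* All four probabilities are Laplace-smoothed, (k + c)/(n + 2c) with
  pseudocount c = 1 by default. Raw proportions would produce infinite
  factors whenever a training count is 0 — which genuinely occurs, e.g.
  no MSS sample with significant bias at a clean marker — while
  smoothing bounds every factor and preserves ordering. The raw counts
  are stored in the model JSON.
* Markers with no usable MSS training sample are dropped with a
  warning; dropped ids are recorded in model provenance.

## Read-pair extraction

Deviation is computed from the CIGAR, not by re-measuring the
homopolymer in read sequence: inserted bases minus deleted reference
bases whose placement intersects the repeat interval. An insertion
counts when anchored at or immediately before a repeat base (an
insertion of the repeat base just left of the run lengthens it). A mate
must span the repeat plus one base each side. A pair counts iff both
mates agree on the deviation; pairs additionally covering a SNP with
agreeing ref/alt bases enter that SNP's allele stratum, so SNP strata
are always a subset of the marker histogram (depth at the repeat and at
the SNP are assessed separately). Third-allele bases are excluded from
the stratification only, so sequencing errors cannot create phantom
alleles. Unmapped, secondary, supplementary, duplicate and QC-fail
records are skipped. No base- or mapping-quality filters are applied by
default. Usability requires ≥ 20 concordant pairs; heterozygosity
requires the least common allele on ≥ 20% of pairs (boundary
inclusive, and a SNP with zero coverage is "not assessable", distinct
from homozygous).

## Statistics

* Fisher's exact test is two-sided by point-probability ordering (the
  dominant convention): sum of hypergeometric probabilities ≤ that of
  the observed table, with a 1e-12 relative tie guard; a zero margin
  gives p = 1. The test suite checks it against exact rational
  enumeration over all tables with margins ≤ 12.
* AUC is the Mann–Whitney statistic with half-credit ties, identical to
  the trapezoid area under the threshold-sweep ROC curve
  ("above threshold ⇒ MSI-H", one point per distinct observed value
  plus sentinels). Confidence intervals use a seeded percentile
  bootstrap (2000 resamples by default) — a pragmatic choice, not a
  canonical one.
* Cohort summaries report sensitivity/specificity with Wilson 95%
  intervals.
* S = 0 is called MSS (ties resolve toward the majority class);
  `min_markers` (default 1) usable observations are required for a
  call, below which the result is "not assessable". With
  `min_markers = 0` an uninformative sample scores the prior log-odds.

## Panel selection

Selection operates on per-repeat summary tables (depths and variant
fractions per pool), not raw WGS: upstream alignment/calling is
external glue, and a documented TSV schema lets the rules be tested
exactly. Rules run in a fixed order (depth, common-SNP overlap,
combined minor-allele probability, low-complexity flag, length-
stratified variant-fraction rule) and the first failing rule is
reported, so exclusion reasons partition the excluded set. "No length
variation" for 7–9 bp repeats means exactly zero variant reads at the
observed depth. Variant fractions count insertions as well as deletions
(length variants of either sign). The low-complexity screen is a
boolean supplied upstream; repeat-masking is out of scope. The
discovery-stage rule keeps a marker iff some MSI-H sample has a
deletion fraction > 5% that is also > 1.5-fold above every normal
sample.

## Mixtures

A mixture at MSI-H proportion p takes, per common marker, frequencies
f = p·f_msi + (1−p)·f_mss over the union of deviation keys and realises
them at depth n = min (default; prevents the deeper sample dominating
rounding granularity) or sum of the two observed depths. Deterministic
mode uses largest-remainder apportionment (counts sum to n exactly,
ties by key order); stochastic mode draws one seeded multinomial.
Allele strata are mixed the same way on the joint (allele, deviation)
cells; a SNP uncovered in one input is empty in the mixture under the
min rule. Heterozygosity is re-called on the mixed counts. The default
grid is 0 to 1 inclusive in steps of 0.025 (41 points) over every
(MSS, MSI-H) cross pair.

## Synthetic data

The generator emulates the data structure the classifier assumes:
negative-binomial read-pair depth (mean 5000 pairs/marker, matching a
~10,000-read amplicon target; dispersion 10); PCR stutter as a
per-repeat-length categorical over deviations −3…+1 whose deletion rate
grows from 0.4% (7 bp) to 13% (12 bp), scaled per library by a
log-normal factor (sigma 0.4) — distributional, not a mechanistic
polymerase model; flanking-SNP genotypes from the panel MAF under
Hardy–Weinberg; and, in MSI-H samples only, a somatic deletion
component on one random allele (biallelic available as a stress flag)
at a Beta-distributed mutant-cell fraction, with length-dependent event
probability (0.45 at 7 bp to 0.90 at 12 bp). The "paper-like" preset
uses these defaults, calibrated so an 8 bp marker separates the classes
modestly and a 12 bp marker almost perfectly; the "separable" preset
(every marker mutated, high mutant fraction) supports
limit-of-detection studies. Presets are calibration targets of the
generator, not measurements.

What the generator does not emulate: FFPE artefact chemistry, base
errors outside the repeat, primer/UMI effects, tumour subclonality
beyond a single mutant fraction, linkage between markers, and germline
repeat-length variants. Passing tests therefore demonstrate
correctness of the computational pipeline and internal consistency of
the model on data satisfying its assumptions — not clinical
performance on real FFPE material.

SAM fixtures: each sample can be rendered as concordant paired-end
alignments over per-marker contigs whose extraction reproduces the
histograms and allele strata exactly. Reconstruction of read pairs
from an observation is only unambiguous with ≤ 1 flanking SNP per
marker; the default panel satisfies this, and emission raises
otherwise.

## Problem sizes

Tests and the acceptance script run at desk scale as the package's own
choice of problem size: cohorts of 30–400 samples, extraction round
trips at reduced depth (~120 pairs/marker, where exactness, not power,
is under test), and LOD grids over 16–64 pairs. The 34 × 36 = 1224
mixture-pair and 41-grid-point design counts are computed at full size.

## Known limitations

* The classifier emits a binary call; MSI-L is deliberately not a
  class.
* Score levels are discrete (each marker contributes one of a few
  factors), so ROC-style post-hoc thresholding of S has limited
  resolution.
* Bias assessment requires heterozygosity; cohorts with low flanking-
  SNP MAFs lose the B term for many samples.
* The conditional-independence assumption across markers is untested
  biology; violations would miscalibrate |S| though typically not the
  ranking.
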