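# Methods

This note records the statistical models, the synthetic-data generator,
the numerical conventions, and the design decisions behind `asedyn`,
together with what the test suite does and does not establish.

## ASE model and tests

Allele counts are arranged as a genes × timepoints × 2 array. All
2T (timepoint, allele) columns of one hybrid are normalized jointly with
median-of-ratios size factors: the reference for each gene is its
geometric mean across columns, genes with a zero in any column are
excluded from the reference set, and the size factor of a column is the
median ratio to that reference. Normalization removes relative depth
differences between columns; an overall scale is not identifiable (and
cancels in allele frequencies). If no gene is nonzero in every column the
size factors are undefined and a `NormalizationError` is raised.

Genes are filtered on raw counts before testing: a gene is removed when
its mean total reads per timepoint is below 20 (strictly — exactly 20 is
kept) or when more than 7 timepoints have zero reads (exactly 7 is kept).
Timepoints with zero reads are undefined for that gene: the frequency is
NaN and the timepoint is dropped from both tests, with the levels test
requiring ≥ 2 and the dynamics test ≥ 4 defined timepoints.

The **levels test** is weighted least squares of `f_i − 0.5` on an
intercept with weights `w_i` (raw totals): `β0 = Σw(f−0.5)/Σw`, variance
`s²/Σw` with `s² = Σw e²/(T−1)`, two-sided t with `T−1` degrees of
freedom. For binomially sampled alleles the conditional variance of
`f_i` is `1/(4 w_i)`, so these weights are the inverse-variance weights
up to the common overdispersion factor absorbed by `s²`.

The **dynamics test** computes
`dw = Σ(w_{i+1}e_{i+1} − w_i e_i)² / Σ(w_i e_i)²` on the residuals of the
levels model in timepoint order; with unit weights this is the classical
Durbin–Watson statistic (verified against the statsmodels implementation
to 1e-12). No analytic null is available for the weighted statistic, so
p-values come from permuting the order of the weighted residuals
(default N = 1000 seeded draws, shared across genes in matrix calls):
the p-value is `(1 + #{|dw* − m| ≥ |dw − m|}) / (N + 1)` where `m` is the
permutation mean — two-sided, since both slow trends (dw < 2) and
alternation (dw > 2) are departures. A normal approximation from the
permutation moments is available as an option. All-zero residuals return
dw = 2 and p = 1 by convention. The smallest attainable p-value is
`1/(N+1)`; genome-wide BH discovery at FDR 0.01 therefore requires either
many genes at the floor or a larger N, which makes the permutation test
conservative at very small FDR.

**Calibration.** The permutation null is exact when the `(f_i, w_i)`
pairs are exchangeable across timepoints — flat expression and constant
library size. When expression follows a trajectory, the variance of the
weighted residuals varies systematically over time and both tests become
mildly anticonservative; this is an inherent property of the weighted
statistics, consistent with the nonzero false-positive counts that the
permutation validation procedure itself reports. The suite therefore
checks exact p-value uniformity on the exchangeable null (KS at 2000
genes) and checks the study-scale validation bounds — mean false
positives over 10 replicates ≤ 7.7 (dynamics, timepoint permutation) and
≤ 2.0 (levels, per-timepoint allele swap) at FDR 0.01 on 4703 genes —
under the full trajectory-generating conditions.

**Permutation validation.** The levels null swaps the two allele labels
of each gene independently at each timepoint with probability 0.5
(preserving totals and per-timepoint depth) and re-runs the full
pipeline, including re-normalization. The dynamics null applies one
random reordering of the timepoint labels to all genes (allele pairs kept
together) and re-runs the test and BH adjustment.

## Synthetic timecourses

Expression trajectories are anchored logistics: the logistic in time is
linearly rescaled to pass exactly through `baseline` at the first
timepoint and `baseline + amplitude` at the last; peak/trough shapes use
a difference of two logistics, linearly detrended so both endpoints sit
exactly at baseline. Anchoring makes delay (t50 shifted) and rate (slope
scaled) allele-2 curves agree with allele 1 exactly at both endpoints, so
those effects are pure dynamics signals; `condition` changes the
post-shift plateau by a log2 factor while sharing the pre-shift plateau,
and `level` multiplies the whole curve by a log2 factor. Effect
directions are randomized per gene (either allele can be the stronger or
earlier one): direction-balanced imbalances keep the median-of-ratios
reference symmetric between the allele columns, as in real hybrids where
roughly half the imbalances favor each parent. A direction-biased
effect set would instead be partially absorbed into the size factors and
shift every gene's frequency — a genuine property of blind normalization
worth knowing about when interpreting level calls.

Counts are negative binomial with variance `μ + α μ²` (α = 0 is Poisson;
default α = 0.01, a typical RNA-seq overdispersion magnitude — per-gene
dispersions are a convention here, not estimates from data). Defaults
mirror the study scale: 4703 genes, 19 timepoints, a metabolic-shift
index of 7, ~600 total allele reads per gene per timepoint, and
per-timepoint library sizes lognormal (σ = 0.2) around that depth,
echoing the reported 1.5–4.8 M per-timepoint range. One root seed feeds
fixed child-stream labels per generator, so outputs are bit-reproducible
and adding a generator never perturbs another.

The generator does **not** emulate read sequences, alignment or mapping
bias, aneuploidy, correlated noise between timepoints, or gene-gene
correlation; passing tests demonstrate the statistical machinery under
the stated count model, not robustness to those artifacts.

## Clustering and transition patterns

Combined-expression profiles are centered and scaled per gene
(mean 0, sd 1); allele-frequency profiles are centered only, preserving
imbalance magnitude. Genes with any missing timepoint are removed first;
zero-variance genes cannot be scaled and are excluded with a warning.
Lloyd's k-means with k-means++ initialization runs 25 restarts (k = 12 by
default, matching the study's group count; the algorithm and restart
policy are this package's choice, as is Euclidean distance). The
transition classifier centers a series and labels it `transition_extremum`
when the largest absolute deviation inside the shift window strictly
exceeds the deviations at both endpoints (by a configurable margin,
default 0), else `environment_dependent`; the dichotomy itself is this
package's operationalization of "peaks at the shift" versus "keeps
diverging".

## Variant burden association

Regions are defined on the coding strand per gene: upstream is the gap to
the adjacent coding sequence, extended past neighbours closer than 5 bp
(or overlapping) to the next gene upstream; coding is the CDS span;
downstream is 80 bp past the stop codon, clipped and flagged at contig
ends. A variant is assigned to a region by its leftmost reference base
(deterministic and strand-independent for InDels spanning a border).
Logistic regressions are fit by IRLS (statsmodels GLM); the full battery
is 6 predictors (SNPs and InDels × three regions) × 10 responses
(5 hybrids × levels/dynamics) = 60 fits at Bonferroni α = 0.05/60.
Complete separation and constant predictors are flagged and the Wald
interval withheld. Odds ratios are per additional variant.

## Reporter library design and analysis

Windows of 130 bp tile the 250 bp upstream of the TSS at a 30 bp step
(five windows when unobstructed), numbered proximal → distal; windows
containing another gene's coding sequence, or a restriction site, are
dropped. For k ≥ 2 variants in a window, each variant is swapped singly
in both directions (2 parents + 2k swaps); k = 1 gives the two parents;
k = 0 one shared construct. Chimeras join the parents at the middle
column of their global alignment — a definition of "center" that is
stable under InDels. Oligos are assembled as
`fwd·RS1·CRE·RS2·pad·RS3·RS4·barcode·RS5·rev` at exactly 200 bp; the pad
compensates InDel-gapped alleles and is a deterministic
construct-id-seeded sequence screened against restriction sites (the
restriction sites and primers themselves are configurable placeholders).
Barcodes are random 10-mers at pairwise Hamming ≥ 2, site-free on both
strands, with pooled base composition within 10 percentage points of
uniform (checked for sets of ≥ 40 barcodes, below which the band is not
meaningful); four barcode replicates per construct.

Barcode counting is exact-substring matching only; mismatched reads are
discarded and tallied. Barcodes are filtered out with zero reads in more
than a third of the RNA samples or a mean below 100 reads (strictly) in
either RNA or DNA. RNA and DNA columns are normalized jointly
(median-of-ratios, blind to the design); expression is normalized RNA
over the barcode's DNA reference, taken as the mean of its two normalized
DNA samples (drawn at the first and last timepoints — used symmetrically).
Zero RNA counts are missing data; a zero DNA reference drops the barcode
with a flag. Because normalization is blind, a library-wide expression
trend is absorbed into the size factors; between-construct ratios are the
identifiable quantity, which is what the allele tests use.

The CRE **level test** collapses each barcode to one value — its
across-timepoint mean expression, natural-log transformed (a variance-
stabilizing choice made here) — and compares alleles with a two-group
linear model, so a single aberrant barcode cannot masquerade as an allele
effect. The **dynamics test** forms the allele-1 share
`m1/(m1+m2)` of the barcode-mean expressions per timepoint, weights it by
total raw reads, and applies the weighted Durbin–Watson permutation test.
Variant tests pool constructs by their allele at the focal variant,
including swap constructs of other variants whose focal-variant genotype
is unambiguous (maximizing replicates); chimera mapping runs the dynamics
test grouped by proximal-half and by distal-half genotype and classifies
the difference as proximal/distal/both/neither at α = 0.05. Chimera
range classification compares, on barcode-mean series over shared
timepoints, the mean Euclidean distance of the chimera to each parent
against the parent–parent distance (`outside` iff greater), and counts
timepoints strictly outside the parental envelope. Region–endogenous
correlation is Pearson on the barcode-mean series, with a nearest-time
mapping (ties to the earlier sample) when the reporter clock is denser
than the RNA-seq clock, and BH across regions at FDR 0.05.

## Variant annotation

PWMs are position probability matrices (MEME minimal input); zero entries
are floored at 1e-3 and the row renormalized (rows without zeros are
untouched, so exact probabilities score exactly). The background has 36%
GC: p(C) = p(G) = 0.18, p(A) = p(T) = 0.32. A placement scores
`Σ log2(p_motif/p_bg)`; the best over all offsets and both strands is
reported and floored at zero ("no better than background"); ambiguous
bases contribute zero. The binding-change annotation of a variant scans
the two alleles' 30 bp flank contexts (clipped at contig ends) with every
motif and reports the maximum across motifs of the absolute score
difference (a signed variant is available). Conservation scores are read
per base: SNPs directly; InDels as the mean of the two flanking sites
plus any interior sites present in the track. Score–effect-group
association uses one-way ANOVA.

## Problem sizes and numerical conventions

The test suite simulates at 200–2000 genes for calibration and power
checks, with 200–2000 permutation draws, and exercises the full 4703 ×
19 study scale in the acceptance tests; the acceptance script uses 1000
permutation draws and 10 validation replicates. Internal coordinates are
0-based half-open everywhere, converted only at the GFF/VCF boundaries;
floats serialize at 6 significant digits; counts round-trip byte-stably
through the TSV writers. Ties in nearest-time mapping go to the earlier
sample; the permutation p-value comparison uses a 1e-12 slack so exact
ties count as "as extreme".

## Known limitations

* The weighted tests are only approximately calibrated when expression
  follows strong trajectories (see Calibration above); the permutation
  validation quantifies the practical false-positive cost.
* The permutation dynamics p-value has granularity 1/(N+1), limiting
  attainable FDR-adjusted significance for small N.
* Blind normalization cannot distinguish a library-wide expression trend
  (or direction-biased ASE across many genes) from depth; only relative
  signals are identifiable.
* The CRE level test with four barcode replicates per allele has modest
  power by construction — the cost of robustness to single-barcode
  offsets; dynamics are unaffected.
* Logistic Wald intervals degrade near separation; such fits are flagged
  rather than reported.
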