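# Methods

## The screen and its statistical model

A paired-allele DNA-pulldown screen measures, for every SNP locus, the
proteins retained by a Ref-allele bait versus an Alt-allele bait.  Each
locus is assayed as two dimethyl-label-swapped replicates: replicate 1 is
Ref-heavy, replicate 2 Alt-heavy, and the stored per-protein log2 ratio is
always heavy-channel over light-channel.  A real allele-specific binder
therefore inverts its stored ratio between replicates, while a labeling or
bead artifact keeps its sign — the swap is the screen's internal control,
and the pipeline exploits it twice: replicate 2 is sign-inverted before
averaging onto the log2(Ref/Alt) scale, and an interactor call must be
individually significant in every observed replicate.

### Ratio-outlier test (modes A and B)

Most proteins in a pulldown bind both alleles equally, so the per-locus
log2-ratio distribution is dominated by a null bulk whose spread is
estimated robustly from percentiles: `r₀` is the median, the right spread
`s₊ = P84.13 − r₀` and the left spread `s₋ = r₀ − P15.87` (the one-sigma
quantiles of a standard normal, so for Gaussian noise both spreads estimate
σ without being inflated by the outliers of interest).  The score
`z = (x − r₀)/s₊` above the median, `(r₀ − x)/s₋` below, is converted to a
two-sided tail probability `p = erfc(z/√2)`.  Mode A estimates one spread
per table; mode B first sorts proteins by mean log10 MS intensity and
partitions them into equal-occupancy bins of at least `min_bin_size`
(default 300) so that the intensity dependence of ratio noise is absorbed
into per-bin spreads.  With fewer than `min_bin_size` observed proteins,
mode B falls back to mode A (logged); with a single bin the two modes are
identical by construction.  Percentiles use linear interpolation between
order statistics and a stable intensity sort, so results are deterministic
across platforms.  A side whose spread is exactly zero while data lie
beyond it raises an error naming the degenerate side.

### Interactor calling

Candidates are proteins with combined-table `p < α` (default 0.01).  A
candidate becomes a call only if every replicate in which it was observed
is itself significant at `α` (and it was observed at least once): a
combined-scale outlier produced by one orientation alone is not an
allele-specific binder confirmed by the label swap.  The reported p-value
is the combined-table p, which stays uniform under the null — the call
rule changes which proteins are reported, not the p-value's calibration.
Proteins observed in a single replicate can still be called (flagged
`single_replicate`) but are excluded from downstream high-confidence
selection by default.  This two-level rule is what keeps the false-
discovery proportion of a spiked screen at the percent level while raw
`p < 0.01` thresholding alone would admit ~1% of all background proteins.

### Batch correction

Batch effects are removed from the combined log2fc matrix (proteins ×
pulldowns) with a parametric empirical-Bayes location/scale adjustment:
per-protein standardization against batch-design fitted means and pooled
variance, per-batch effect estimates, shrinkage toward the cross-protein
batch prior (normal prior on locations, inverse-gamma on scales,
hyperparameters by method of moments, iterative conditional solution), and
back-transformation.  The implementation is NaN-aware: rows with fewer than
two observed values in any batch are passed through unadjusted and flagged,
and single-batch input is returned unchanged.  On complete matrices it
agrees with scanpy's parametric ComBat to ~1e-3 (verified in the test
suite).  Degenerate hyperpriors (zero between-protein variance of the batch
effects, as in noise-free location shifts) disable pooling and fall back to
exact per-protein removal.

### Imputation

Missing ratios are replaced per column by draws from
`Normal(mean − d·sd, (w·sd)²)` of the column's observed values, with
defaults `d = 1.8`, `w = 0.3` — the convention for left-censored MS
missingness, placing imputed values in the low tail so they cannot create
spurious strong calls.  Columns with fewer than three observed values
cannot provide moments and raise an error.  Imputation runs after replicate
combining (on the per-locus combined columns); replicate-level support
tests use only observed measurements, so imputed cells never confirm a
call.

### Combined accessibility / fold-change statistic

For prioritization, each locus is summarized by its mean DNase I read count
across accessibility samples (the study design pools 15 fetal large
intestine tissues and 12 colorectal cancer cell lines, hence the default of
27 samples) and z-scored across loci; each interaction by its absolute
log2 fold change, z-scored across **all quantified interactions** of the
screen — not only the significant calls, so a strong allelic switch is
measured against the bulk of inert protein–DNA pairs.  The two z-scores
are averaged and `p = 1 − Φ(z̄)` (one-sided upper tail: |log2FC| is
non-negative, so only large z̄ is interesting; allele direction is carried
separately by the sign of the fold change).  Z-scores use the n−1 sd
convention; an all-equal input yields all-zero z (logged).  An event is
*selected* when `p < 0.05` **and** it is a replicate-confirmed interactor
call; ranking is by ascending p with ties broken by descending |log2FC|,
then ids.  No multiple-testing correction is applied by default; a
Benjamini–Hochberg column is available (`add_bh=True`).  DHS means use raw
counts; a reads-per-million option exists behind `normalize_depth`, and
per-SNP fold-change z-scores behind `per_snp_fc`.

### Allelic imbalance

Ref/Alt read counts at a heterozygous site are tested against background
counts with Fisher's exact test; the two-sided p sums the probabilities of
all 2×2 tables with the observed margins whose point probability does not
exceed the observed one (the standard exact convention, delegated to
scipy and verified in the tests against exact rational enumeration to
1e-12).  Without a background, a 50:50 split at matched depth (the
heterozygous genomic-DNA expectation) is substituted and logged.  The odds
ratio is the sample cross-product ratio with the Haldane–Anscombe 0.5
correction (flagged) when any cell is zero.

### 4C reduced genome and windows

The 4C alignment target is the set of 30-base sequences immediately 3′ of
each primary restriction site on each strand (the minus-strand flank is the
reverse complement of the 30 bases 5′ of the site).  Digestion is an exact
substring scan: palindromic recognition sequences (NlaIII `CATG`, CviQI
`GTAC`) are scanned on the plus strand only; non-palindromic ones also as
their reverse complement.  "Uniquely mappable" is implemented as exact
string uniqueness of a site's flanks within the pooled flank multiset — a
deliberate, documented proxy for an external-aligner mappability
evaluation, not a claim of equivalence.  Sites within one flank length of a
contig edge are dropped and logged.  Interaction counting tiles 2.5-kb
windows per contig (default non-overlapping; a sliding step is available),
assigns each read to the window containing its start, normalizes to
reads-per-million with viewpoint-window reads excluded from the total, and
reports the between-condition log2 ratio of normalized counts with
pseudocount 1.  The statistical interaction caller of dedicated 4C packages
(background fitting, significance) is intentionally out of scope: only
counts, normalization and differences are produced.  Coordinates are
0-based half-open throughout.

## Synthetic data: what it emulates and what it does not

The generator reproduces the screen's *design*: 116 loci by default, two
label-swapped replicates per locus, a shared universe of 1000 background
proteins, 20 spiked allele-specific binders with true |log2FC| = 4 and
per-binder random sign, replicate noise sd 0.3, log-normal MS intensities
(log10 ~ Normal(7, 1) — an arbitrary but realistic span; only relative
binning matters), missing-not-at-random ratios (bottom-quartile intensities
missing with probability 0.1), optional per-batch Normal(0, 0.5) offsets,
and negative-binomial DHS counts (mean 20, dispersion 0.1, 27 samples,
10-fold enrichment at designated loci).  Batch offsets are applied on the
oriented Ref/Alt scale so that they survive label-swap combining and are
removable at the correction stage; purely instrumental heavy/light offsets
would cancel in the swap and leave nothing to correct.  The replicate count
and batch layout are parameters, not constants.

What it does **not** emulate: peptide-level quantification and protein
inference, correlated protein abundances, intensity-dependent ratio
variance (each replicate's noise is homoscedastic, so mode B's binning is
exercised structurally rather than statistically), interaction competition
between TFs, and real DHS depth variation between samples.  Passing tests
therefore demonstrate that the algorithms are implemented correctly and
calibrated under the stated noise model, not that the screen's biological
error rates transfer to real extracts.

Determinism: every generator and stochastic stage derives its RNG seed from
one master seed hashed with a stage name, so identical spec + seed
reproduces every table byte-for-byte while stages remain mutually
independent.

## Problem sizes used in tests and the acceptance script

Simulation-based properties run at sizes chosen to make the checks sharp
yet quick: spike recovery uses 10 screens of 1000 proteins with 20 spikes;
null calibration 20 spike-free screens of 500 proteins; the end-to-end
ranking check full 116-locus × 1000-protein screens; null-selection
checks 20 screens of 6 loci × 200 proteins; the digestion oracle a 100-kb
contig; the exact-test oracle every 2×2 table with grand total ≤ 30
(hence every margin ≤ 30).  The whole suite runs in well under a minute on
one core.

## Known limitations and open choices

* Whether the study's 731-type event count is taken before or after
  restriction to annotated TFs is ambiguous upstream; the pipeline reports
  both counts (`n_calls`, `n_calls_tf_annotated`).
* The ratio-outlier test is exposed as both mode A and mode B (the
  conventional defaults of the software the procedure originates from); the
  bin size is not specified upstream and defaults to 300.
* The stage at which batch correction is applied (before vs after replicate
  combining) is configurable; the default corrects the combined matrix.
* The exact background used for allelic-imbalance tests (input chromatin,
  genomic DNA, or theoretical 50:50) is an open choice; matched-depth 50:50
  is the default with an explicit override.
* Fold-change z-scores pool all interactions screen-wide by default; a
  per-SNP variant is available but changes the meaning of the ranking for
  loci with few interactions.
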