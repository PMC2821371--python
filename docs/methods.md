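# Methods

This note documents the statistical procedures implemented in `zcomp`,
the generative model behind the synthetic data, the defaults of every
tunable parameter, and the numerical conventions chosen where the
procedure leaves room.

## The scientific setting

Birds carry ZZ (male) / ZW (female) sex chromosomes. Without dosage
compensation, a Z-linked gene is expected at a male:female (M:F)
expression ratio near 2, driven by copy number; compensated genes sit near
1. The pipeline quantifies, per probeset of a normalized expression
matrix: whether it is sex-biased at all (SAM + ratio band), whether a
Z-linked probeset is compensated (ratio band), and how compensation is
arranged along the chromosome (running-average and amplitude profiles,
with particular interest in the MHM locus on Zp where compensated genes
cluster). Gene-list comparisons use a Monte-Carlo overlap test; functional
characterization uses hypergeometric term enrichment.

## Detection filter

A probeset is retained when it is called Present in at least
`ceil(min_present_fraction × n_samples)` arrays (default fraction 0.5, so
9 of 18). Marginal calls do not count as Present. The rule is idempotent
and order-preserving; an empty result warns rather than fails.

## M:F ratios

Per probeset, linear intensities are clipped up to `floor_intensity`
(default 1.0, in MAS5-scale units) and the ratio of the male mean to the
female mean is taken — the ratio of means, not the mean of ratios. The
floor keeps near-zero values from producing unbounded ratios; with it,
`log2_mf` is always finite. Ratios are invariant to sample order and to a
global positive rescaling of the matrix. Whether ratios should use linear
or log-scale means is a genuine choice; linear ratio-of-means is used
because it is the natural reading of "ratio of mean expression values",
and the classification bands are stated on that scale.

## SAM (two-class unpaired)

Computed on `log2(clip(intensity, floor))`; fold changes are reported as
ratios of linear means so they agree with the M:F ratio table.

* statistic: `d = (x̄_M − x̄_F)/(s + s0)` with
  `s = sqrt[(1/n_M + 1/n_F)(SS_M + SS_F)/(n_M + n_F − 2)]`.
* fudge factor `s0`: by default the cv-minimization rule — candidates are
  the {0,5,…,95} percentiles of `s`; for each, the median absolute
  deviation of `d` is computed within 100 `s`-quantile windows and the
  candidate minimizing the coefficient of variation of those spreads wins
  (ties → smallest candidate; degenerate scatter → `s0 = 0` with a
  warning). A `fixed_percentile(q)` strategy is also available. At least
  100 probesets are required for cv-minimization.
* permutations: distinct sex-label arrangements. All `C(n, n_M)` are
  enumerated when that count is at most `exhaustive_cap` (default 50000 —
  so the 18-array 9 v 9 design, C(18,9) = 48620, is exhaustive and free of
  sampling noise); otherwise `n_permutations` (default 1000) distinct
  arrangements are sampled uniformly without replacement, with the
  original labeling force-included by default (`include_original`).
* calling: observed order statistics `d_(i)` are compared with their
  permutation means `d̄_(i)`. For a threshold δ, `cut_up` is the smallest
  `d_(i)` with `d_(i) − d̄_(i) ≥ δ` (symmetrically `cut_low`); everything
  beyond the cutoffs is called, positive tail = male-biased.
* FDR(δ): the median (configurable to mean) over permutations of the
  number of permuted `d` values beyond the cutoffs, divided by the number
  of calls, capped at 1. No proportion-of-nulls (π0) correction is
  applied, matching the original formulation. The δ grid is 60 evenly
  spaced values up to `max|d_(i) − d̄_(i)|`.
* q-value: the smallest FDR(δ) among thresholds at which the probeset is
  called; probesets never called keep q = 1. Called flags are set at the
  smallest δ with FDR ≤ `target_fdr` (default 0.05); if no δ reaches the
  target, nothing is called.
* determinism: observed ties in `d` are broken by probeset id; all
  sampling is driven by the configured seed.

The permutation count and `s0` policy of any given historical analysis are
generally unknowable; both are explicit configuration here, and the
defaults above are assumptions, not estimates.

## Classification bands

* Bias funnel (two stages, counts reported separately): stage 1 requires a
  SAM call at the target FDR in the matching direction; stage 2 requires
  M:F strictly between `biased_min` = 1.5 and `biased_max` = 3.2 for male
  bias, and F:M > 1.5 with **no** upper bound for female bias (female
  excesses of W-linked genes can exceed 100-fold, so an upper bound would
  be wrong there; the 3.2 cap describes the male band only).
* Compensation classes (ratio only, no FDR stage): compensated for M:F in
  [0.8, 1.3], non-compensated for M:F ≥ 1.5, intermediate otherwise. The
  printed band edges do not state open/closed endpoints; both endpoints
  are taken inclusive here and tested as such. Every ratio maps to exactly
  one class.
* Chromosome summaries exclude chromosome 32 (unannotated) and W (female
  specific) as well as the unplaced strata; Z-versus-autosome shifts are
  tested with the Wilcoxon rank-sum on log2(M:F) (exact enumeration for
  tie-free samples with n ≤ 12, otherwise the normal approximation with
  tie and continuity corrections, via `scipy.stats.mannwhitneyu`).

## Chromosomal profiles

Probesets are sorted by position (ties broken by probeset id; probesets
lacking positions are dropped with a logged count). The running average
uses a boxcar of `window` = 30 consecutive log2 ratios at step 1, each
window placed at the median position of its members (mean of the two
central positions for even windows); output length is n − window + 1. The
amplitude profile applies the same windowing to |log2 M:F|, which
separates genuine compensation (low amplitude) from sign-averaging.
Profiles are computed on the log2 scale throughout, matching the scale of
the distribution histogram (default bin width 0.1 log2 units; modes are
bins exceeding both neighbors). The MHM window coordinates are
configuration inputs, not constants. `region_contrast` compares values
inside a window against the rest by rank-sum (continuous values) or by the
overlap permutation test (class indicators) and requires at least 5
probesets inside and a non-empty outside.

## Overlap permutation test

Both sets are re-drawn uniformly without replacement from the universe in
each of `n_sims` = 10000 simulations and the overlap recorded;
`empirical_p = (#{sim ≥ observed} + 1)/(n_sims + 1)` (the add-one estimate
avoids zero p-values, so p ∈ [1/(n_sims+1), 1]). The simulated overlap is
hypergeometric, which the tests exploit as a closed-form oracle. Universe
choice matters and is the caller's: the filtered transcriptome for
differential-expression lists, the expressed-Z set for compensation lists.

## Enrichment

Probesets are collapsed to genes by keeping, per gene, the
highest-annotation-quality probeset (exact ties broken uniformly at random
under a seed; the gene set does not depend on the winner). Per term with
at least one background gene, the raw p is the exact hypergeometric tail
P(X ≥ k) with (N, K, n, k) = (background size, background term genes,
query size, query term genes); values that underflow double precision are
clipped to the smallest positive normal float so p stays in (0, 1].
Benjamini–Hochberg runs over all terms represented in the background
(statsmodels' `fdr_bh`, validated in tests against the step-up closed
form). Only over-representation is computed. Genome versus transcriptome
background is the caller's choice of the background gene set; neither
direction of inequality between the two is guaranteed.

## Synthetic data generator

Per probeset, a true log2 abundance (the male expectation) is drawn from
N(`baseline_log2_mean`, `baseline_log2_sd`); class determines the female
expectation: equal for autosomal and compensated-Z probesets, reduced by
log2 of the configured ratio for non-compensated Z (males are never
boosted — dosage differences are realized purely by female attenuation),
and W probesets invert the pattern with the *male* channel attenuated by
`w_fm_log2`. Observations add N(0, `noise_log2_sd`) on the log2 scale, are
exponentiated, and `detection_floor` is added so linear values are
positive. Detection is Present with logistic probability
`1/(1 + exp(−slope·(μ − midpoint)))` in the noise-free log2 intensity.
Positions are uniform per chromosome; the compensated count is fixed at
`round(frac_z_compensated · n_z)` exactly, and *which* probesets are
compensated is drawn without replacement with weights elevated inside
`mhm_window` by `(frac + boost)/frac`, so class counts are deterministic
while the window is enriched in expectation. Identical seeds give
bit-identical outputs; different seeds change noise but not class counts.

Defaults (free parameters; plausible for MAS5-scale data, not estimates of
any particular dataset): 9 samples per sex; 3000 autosomal + 689 Z + 30 W
probesets (the Z count matches the scale of an expressed-Z set on a
chicken array; the autosome count is scaled down for tractable tests — a
real filtered transcriptome is ~4× larger); baseline log2 mean 7, sd 1.5;
noise sd 0.25; compensated fraction 0.3; non-compensated M:F 2.0; Z length
75 Mb with the MHM-like window at 25–30 Mb and compensated-probability
boost 0.5; W female excess 6 log2 units; detection midpoint 3.0 (log2),
slope 1.5, floor 1.0.

What the generator does *not* emulate: probe-level effects, array spatial
artifacts, batch structure, cross-hybridization, annotation errors, and
the long-tailed ratio heterogeneity of real Z genes (real data show
intermediate ratios and female-biased autosomal genes; the latter can be
planted via `extra_effects` but are off by default). Passing tests
therefore demonstrate correctness of the statistical machinery under the
stated model, not biological completeness.

## Problem sizes used in validation

The test suite and the acceptance script size their simulations so a full
run stays lightweight: the type-I study uses 50 null simulations of 1000
probesets with 200 sampled permutations each; parameter recovery uses
2000 Z probesets; the exhaustive-oracle study uses the 4 v 4 design where
all 70 arrangements can be enumerated; the acceptance script runs the
default probeset complement with the fully exhaustive 48620-permutation
null. These sizes are the package's chosen validation conditions and are
stated here so they can be scaled up verbatim.

## Known limitations

* The SAM FDR uses the raw median false-call count (no π0); with many true
  positives the estimate is conservative.
* The female-bias funnel reuses the negative tail of the single SAM run
  rather than re-running SAM on F:M-transformed data; with a symmetric
  statistic the two are equivalent up to sign, but a historical analysis
  that ran them separately could differ in its permutation draws.
* Probesets with multiple genomic alignments must be given a single
  position in the annotation input; the pipeline does not resolve
  multi-mapping.
* Enrichment takes term annotations as already propagated (no ontology
  graph handling).
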