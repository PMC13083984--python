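# Methods

## Model

Plasma cfDNA is overwhelmingly of hematopoietic origin and copy-neutral;
tumor-derived fragments add or remove coverage wherever the tumor genome
carries copy-number aberrations. For a genomic bin of absolute tumor copy
number `c` in a sample with tumor fraction `t`, expected relative coverage
is `(1−t) + t·c/2`, so the centered linear deviation is `t(c−2)/2` — linear
in `t`. The whole method rests on this linearity: the deviation profile of a
low-TF query is a scalar multiple of the profile of a high-TF reference from
the same tumor, and that scalar, times the reference's tumor fraction, is
the query's tumor fraction.

Assumptions worth stating explicitly: a diploid copy-neutral background (the
genome-wide median is treated as copy number 2); the reference and query
share the same CNA landscape (clonal evolution between biopsies degrades the
fit and biases the score downward, never upward); and the user-supplied
reference TF is accurate, since the query TF estimate is proportional to it.
Deviations are kept on the linear copy-ratio scale rather than log2 because
ctDNA signal is linear in TF only on the linear scale.

## Pipeline stages and parameters

**Bin grid.** Fixed-width windows (default 100 kb) stepped every 10 kb
(`bin_width`, `step`; width must be a multiple of step). Bases with
mappability score < 0.2 (`mappability_cutoff`) are masked — this removes
centromeres, telomeres and repeat territory — and only windows lying
entirely in unmasked territory are kept, so each retained bin's mean
mappability is at least the cutoff. Only autosomes are used; bins truncated
at chromosome ends are dropped so all bins are exchangeable in the count
model. Per-bin mappability is the mean of the track over the bin (the
aggregation is a design choice; base-level tracks do not dictate one). GC is
computed from a FASTA (all-N bins dropped), replication timing from a
bedGraph/bigWig with chromosome-median imputation for uncovered bins.

**Counting.** Reads with MAPQ ≥ 30 (`mapq_min`), excluding duplicates,
secondary, supplementary and unmapped records, are counted into every bin
they overlap (a read lands in up to `bin_width/step` bins). With in silico
size selection (`fragment_max`, typically 150 bp) only read 1 of proper
pairs with `0 < |TLEN| < fragment_max` is counted, so each short fragment
counts once; size selection enriches tumor-derived fragments, which run
shorter than hematopoietic cfDNA, and raises signal amplitude.

**Bias correction.** `log2(count + 1)` is sequentially detrended against
GC, mappability and replication timing (in that order). Each trend is a
cubic B-spline (5 interior knots at covariate quantiles) fitted to
per-stratum medians of ~100 covariate-quantile strata, with Tukey-biweight
reweighting (2 passes). Three safeguards keep the bias model from absorbing
copy-number signal, which would compress deviation amplitude at high TF:
(1) a stratum whose median deviates from the running median of its
neighbors by more than 5 robust SD is replaced by that running median —
this catches strata hijacked by a large CNA event, especially at covariate
boundaries where the spline has full leverage; (2) each trend is fitted
twice, the second time only on bins within 2.5 robust SD of the first-pass
residual median (copy-neutral territory); (3) the evaluated trend is
extended linearly beyond the outermost strata and clamped near the range of
the stratum medians. A covariate that is constant or missing skips its step
with a log message.

**Centering.** `deviation = ratio / median(ratio) − 1` with
`ratio = 2^log2_ratio`; the genome-wide median deviation is zero by
construction. With a very aberrant genome (high TF) the global median sits
slightly off the copy-neutral center — a percent-level amplitude
compression at the lowest depths that is visible in the same-tumor
depth-robustness experiment and accepted as the price of a fully
assumption-free centering.

**Segmentation.** Per chromosome, penalized least-squares changepoint
detection (PELT: exact optimal partitioning with pruning; pruned candidates
are removed only after `min_seg_bins` further positions, which keeps the
program exact under a minimum segment length — plain PELT pruning is
slightly suboptimal there). Penalty `β = penalty_scale · σ̂² · ln(n)` with
`penalty_scale = 5` and σ̂ the MAD-based noise scale of first differences;
minimum segment length `min_seg_bins = 5` so segment medians stay stable.
Segment value = median deviation of member bins; the same bin ranges are
projected onto the query. Ranks ascend by reference value with ties broken
by genomic position.

**Similarity score.** The objective
`min_{x≥0} Σ w_i (a_i x − b_i)² + λ|x|` is one-dimensional, so the exact
minimizer is the soft-thresholded projection
`x* = max(0, (Σ w a b − λ/2) / Σ w a²)`; a bounded scalar minimizer serves
as an independent oracle in the tests. Weights: `CN_ref = clip(2 +
2·ref_value/TF_ref, 0, 20)`; `SD_ref`/`SD_qry` are the standard deviations
of segment values within the segment's chromosome; `w = 1 + CN_ref ·
SD_qry/SD_ref` capped at 10, and `w = 1` for single-segment chromosomes or
degenerate SDs. Bins inherit their segment's weight. λ defaults to the 95th
percentile of `|2 Σ w a b|` over 200 simulated flat-noise queries matched
to the query's mean bin count (negative-binomial, same dispersion), so a
tumor-free query returns exactly zero with ~95% probability; it can be fixed
via config. The score is reported unclipped — values above 1 mean the query
carries more tumor DNA than the reference.

**Significance analysis.** Kendall tau-b between reference and query
segment values; Dunn's test between every segment pair of the query (joint
ranking of all bin deviations, tie-corrected rank-sum z, two-sided normal
p), Šidák-adjusted with `m = S(S−1)/2` computed as `-expm1(m·log1p(−p))`
for numerical stability. The rank-ordered matrix is sectioned into
within-lower-half, within-upper-half and cross-half cells (lower half =
ranks `1..⌊S/2⌋`; with odd S the middle segment joins the upper half). The
one-sided Mann–Whitney contrasts take the alternative that within-half
p-values are stochastically greater than cross-half p-values — with ctDNA
present, the low-versus-high comparisons are the significant ones. The
eight features feed an RBF SVM (C = 1, standardized features, balanced
class weights, fixed seed). Because bins overlap in real grids, Dunn's test
sees correlated observations; the classifier is trained on data with the
same correlation structure, so the features remain comparable even though
the raw p-values are not calibrated probabilities.

**Combined call.** Positive iff `TF_query ≥ 0.002` (`llod_threshold`) AND
the SVM predicts True. Molecular recurrence in a longitudinal series is the
first time point that is positive and has a TF estimate strictly above the
preceding time point (0-based index returned). When no classifier model is
supplied the pipeline reports the features, leaves the SVM field null and
flags the call as TF-threshold-only.

## The synthetic-data generator

The simulator emulates the study design this method is validated on:
piecewise-constant tumor genomes diluted into flat diploid background and
sequenced shallowly.

* **Genome.** 22 autosomes with hg38-proportional lengths scaled to ~1 Gb,
  tiled with non-overlapping 100 kb bins (~10,000 bins). Non-overlapping,
  because at the bin-count level overlapping stepped windows share reads;
  drawing independent counts on an overlapping grid would overstate the
  genome's information content about tenfold. GC varies smoothly in
  [0.3, 0.7], mappability is 1, replication timing is a smooth random walk,
  so the correction code paths run exactly as on real data.
* **Truth profiles.** Random non-overlapping segments in states
  {0, 1, 3, 4, 6} (weights 0.10/0.35/0.30/0.15/0.10) placed until the target
  genomic-instability level is reached (default studies use GI 0.4, a
  high-instability tumor), always including one focal event (< 30 bins).
* **Counts.** `μ_i = reads_per_bin · [(1−t) + t·c_i/2] · gc_bias_i`, drawn
  negative-binomial with variance `(1 + d)·μ` and `d = 0.1` — mild
  overdispersion over Poisson, matching the residual variance of corrected
  sWGS 100 kb bins. The dispersion enters as an excess-variance fraction
  rather than an NB2 `α` because the latter at any fixed value cannot
  represent near-Poisson bin noise across the depth range used here.
  A 1x depth equivalent is 1000 expected reads per 100 kb bin (100 bp
  reads); depth down-sampling of one run is binomial thinning, which
  preserves the run's sampling noise exactly as read-level down-sampling
  does.
* **Read-level fixtures.** Small single-chromosome paired-end BAMs with
  MAPQ, pairing flags and template lengths, tumor fragments drawn shorter
  (mean 145 bp vs 166 bp), exercise counting and size selection end to end.

What the simulator does *not* model: fragment-level GC effects,
alignment/mapping artifacts, FFPE damage, clonal hematopoiesis CNAs, or
clonal divergence between reference and query. Passing tests therefore
demonstrate the statistical machinery under the stated noise model, not
robustness to those real-data phenomena.

All generators are pure functions of their parameters and a seed; replicate
seeds are spawned deterministically from a master seed.

## Study sizes used in tests and the acceptance script

Simulation studies run on the ~10,000-bin genome at 1x equivalent: the
dilution ladder uses TF ∈ {0.1%, …, 10%} with 20 replicates per level; the
detection-limit ladder {0.05%, …, 1%} with 30 replicates; depth robustness
compares 10 binomially-thinned replicates at each of 0.2x–5x against a
5x reference; separation at 2% TF uses 50 admixtures versus 50 controls;
null specificity uses 500 tumor-free queries; the classifier trains on 100
replicates at each of 7 positive TF levels plus 100 tumor-free negatives.
These sizes make every study reproducible on a laptop in minutes.

## Numerical choices and degenerate inputs

* Pseudocount +1 inside `log2` bounds zero-count bins.
* Median (never mean) per segment and for centering; rank ties broken by
  genomic position for determinism.
* Zero-noise segmentation: σ̂ is floored at 1e-8 so the penalty stays
  positive and the minimal true segmentation is recovered exactly.
* A flat reference (`Σ w a² = 0`) is a hard error — the method is undefined
  without reference CNAs.
* Degenerate Dunn pairs (zero variance) get p = 1 with a warning; a
  feature vector containing NaN is rejected by the classifier with the
  feature named.
* Chromosomes shorter than `min_seg_bins` become single segments with a
  warning; constant covariates skip their correction step.
* Identical config + inputs + seed give byte-identical reports; the config
  hash is embedded in every report.

## Known limitations

* The TF estimate is relative: it inherits any error in the user-supplied
  reference TF, and a reference whose CNAs are undetectable (very low
  purity) is unusable.
* At 0.2x and below, global-median centering on a highly aberrant genome
  compresses deviation amplitude by a few percent, which is visible as
  same-tumor scores slightly under 100%.
* Dunn p-values on overlapping-window grids are anti-conservative in
  absolute terms; they are used only as ranked features, never as
  calibrated significance statements.
* The default classifier is simulator-trained; applying it to a materially
  different noise regime (different depth, bin size, or library chemistry)
  warrants retraining with the `train` entry point.
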