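# Methods

This note records the models, the numerical choices, and the design
decisions behind `gfzones`, and what the synthetic-data tests do and do
not establish about behaviour on real data.

## Per-SNP forests

Each SNP's diploid dosage (0/1/2) over all individuals is regressed on
the 20 annual climate predictors with a bootstrap ensemble of CART
regression trees: 200 trees (the point where ensemble error typically
plateaus), variance-reduction split criterion, 6 predictors tried per
split (⌊20/3⌋, the regression default), minimum leaf size 5, bootstrap
samples of size n. Individuals — not population allele frequencies —
are the unit of analysis, so populations contribute in proportion to
their sampling. Missing calls drop that individual for that SNP only
(complete-case fitting, no imputation); SNPs with more than 20% missing
calls, fewer than 30 complete cases, or zero dosage variance are
skipped and logged.

Out-of-bag R² = 1 − MSE_oob / Var(y), with MSE_oob over the samples
that have at least one out-of-bag prediction. Samples never out of bag
(possible at very small tree counts) are excluded; if fewer than half
the samples have an OOB prediction, the fit is flagged and treated as
non-predictive. A SNP is retained iff its OOB R² is strictly positive.

### Engine

Thousands of per-SNP forests share one predictor matrix, so the engine
(numba-compiled) quantile-bins each predictor once — up to 255 bins;
with ≤ 255 distinct values the binning is exact, otherwise split
thresholds are the quantile boundaries — and all forests operate on the
shared integer codes. Randomness is an explicit xorshift64* stream
seeded per forest, making fits bit-reproducible across platforms. Each
split's impurity reduction is recorded as
(n_node / n) · (Var_node − w_L Var_L − w_R Var_R), the same units as
impurity-decrease importance in standard implementations. The engine is
validated in the test suite against an independent random-forest
implementation (OOB R² within 0.05, matching importance ranking on
planted signals, negative-null behaviour on permuted responses) and
against exhaustive split enumeration on forests small enough to tally
by hand.

## Aggregation into turnover functions

For a retained SNP s, the raw importance of predictor p is the sum of
its split impurity reductions; the SNP's OOB R² is partitioned across
predictors proportionally to raw importance (share(s, p)), so that
Σ_p share(s, p) = R²(s) exactly (checked at relative 1e−9). Each
SNP's splits on p are rescaled to sum to share(s, p); aggregation over
SNPs is a plain sum divided by the number retained. Consequences used
as invariants throughout the suite:

- overall importance of p = mean partitioned share over retained SNPs;
- each aggregate turnover curve ends exactly at its predictor's overall
  importance, and the totals across predictors sum to the total mean R².

Along each predictor, importance and data densities are computed on 101
equal-width bins spanning the observed range (bin count configurable).
d(x) is the sample histogram normalized to integrate to 1. The
standardized importance is f(x) = I(x) / max(d(x), 0.01·max d); bins
below the 1% density floor are flagged, preventing blow-ups where the
sampled climate is sparse. The reference R implementation's internal
density smoothing is not published at this granularity; the binned
estimator here is this package's own declared scheme.

Aggregate turnover curves are the cumulative sum of f rescaled to end
at the predictor's overall importance; per-SNP curves are exact
staircases over that SNP's weighted split values. Evaluation clamps to
0 below the observed range and to the total above it; linear
interpolation between breakpoints is the default for raster
transformation, with right-continuous staircase evaluation available
(and used by the oracle tests, where curves must equal a brute-force
split tally exactly).

## Grid transformation, PCA, RGB

Transforming a climate raster evaluates every aggregate turnover
function at every valid cell, producing one band per predictor in
cumulative-importance units; the transformation is monotone bandwise by
construction. PCA is fitted on all masked-in grid cells (the map is the
object of interest; a flag allows site-only PCA as a sensitivity
check), on centred but **unscaled** bands: the bands already share the
importance scale, and variance-scaling would erase exactly the
importance weighting that makes dominant predictors dominate the map.
Component signs are fixed by making each component's largest-magnitude
loading positive, so maps reproduce across runs and platforms. The RGB
map rescales the top three PC scores to [0, 255] by a 2nd–98th
percentile stretch by default (min–max available); stretch bounds are
recorded so colors are reproducible; masked cells are transparent;
constant score bands map to mid-gray with a warning.

## Zonation

PAM (k-medoids) runs on the Euclidean distances of the top-3 PC scores
(91–92% of transformed variance in the motivating application;
clustering space configurable). Instances small enough to enumerate
(C(n, k) ≤ 20 000 medoid subsets) are solved exactly; larger instances
use BUILD initialization plus steepest-descent SWAP, best of 5 restarts
(one BUILD, four seeded random starts). Distances come from direct
coordinate differences rather than the square-expansion identity, whose
cancellation error can flip near-tie medoid choices.

Within-cluster variation is reported scale-free:

    W(k) = (mean distance to the assigned medoid)
           / (RMS distance of all points to the single best medoid),

so W(1) ≤ 1 and curves are comparable across data sets; the reference
workflow never defines its W units, so magnitudes are comparable only
qualitatively. The 2..16 scan warm-starts each k from the (k−1)
solution extended by the best greedy addition, which SWAP can only
improve — so W(k) is non-increasing by construction, and the k = 1
solution (computed internally) defines the first reduction r(2).

"Adding one more cluster explains substantially less" is
operationalized as: chosen k is the smallest k in the scan with
r(k+1) < θ · median(r(2..k)), default θ = 0.5; if no k qualifies the
scan returns its maximum k with a no-elbow flag, and the full W/r curve
is always written so users can override. The rule is invariant to
uniform rescaling of the reductions. Note its arithmetic on smooth
curves: for geometric decay r(k) = c^k the criterion ratio is c^(k/2),
so slow decay (c ≳ 0.97) never fires within 2..16 while c = 0.9 fires
at k = 14 — an "elbow" only in the rule's technical sense. Landscapes
with genuinely continuous structure therefore tend to yield small k or
a no-elbow flag rather than a confident intermediate k.

For rasters, PAM runs on a seeded random subsample of valid cells
(default 4 000; PAM is quadratic in time and memory, and at 4 000
points a full scan costs seconds while the medoid estimates are already
stable) and every valid cell is then assigned to its nearest medoid,
ties toward the lowest zone id. Zone labels are relabelled 1..k by
descending area; optional majority-filter smoothing exists but is off
by default and logged when applied.

## Zone comparison

Zone maps must be co-registered on one equal-area grid (nearest-
neighbour resampling to the coarser grid is the caller's
responsibility; geometry mismatches are errors). Overlap is equal-area
cell counting — exactly reproducible, no polygon-precision ambiguity.
A correspondence lists (gf-zone-set, reference-zone-set) pairs, so
many-to-one pairings are expressible. The rate divides the overlapping
area by the **reference** zones' full area by default ("the percentage
of the area in a zone that overlapped"); gf-side and union denominators
are available, as the wording that motivates the default is ambiguous.
The averaged rate is the area-weighted mean over pairs (simple mean by
flag). Forward comparison overlaps the chosen-k map against a
reference; backward comparison re-delineates at the reference's k
through the identical pipeline, so forcing k to the forward choice
reproduces the forward map bit-for-bit.

## Synthetic landscapes

The generator emulates the study design the pipeline targets:

- **Climate**: 20 Gaussian random fields smoothed to a configurable
  correlation length (default 15 cells), linearly mixed to a target
  inter-variable correlation (default constant 0.5 — annual climate
  summaries are strongly cross-correlated), then affinely rescaled into
  plausible western-Canada ranges per variable (MAT −7.3..10.3 °C and
  MAP 225..8769 mm follow the reported span of the motivating study
  area; the remaining 18 ranges are realistic magnitudes chosen once).
- **Sampling**: population centres drawn without replacement from valid
  cells; samples inherit their cell's climate exactly. Default design
  50 populations × 20 individuals; an uneven total (e.g. 281
  populations, 1906 seedlings) is supported.
- **Adaptive SNPs**: dosage ~ Binomial(2, logistic(a + b·z)) with z the
  standardized driver variable; slopes |b| ∈ [1.5, 3] with random sign,
  intercepts ∈ [−0.5, 0.5]; optionally an additional Balding–Nichols
  deviation to study confounding (off by default).
- **Neutral SNPs**: ancestral frequency π ~ U(0.1, 0.9), population
  frequency ~ Beta(π(1−F)/F, (1−π)(1−F)/F) (Balding–Nichols; F is the
  expected FST, default 0.1), dosages ~ Binomial(2, p_pop).

All draws come from one seeded generator in a fixed call order;
identical configurations are bit-identical. The generator does **not**
emulate linkage disequilibrium (loci independent), coalescent or
isolation-by-distance spatial autocorrelation of neutral frequencies,
genotyping error, or ascertainment bias of SNP arrays. Passing tests
therefore demonstrate correct mechanics and behaviour under the modeled
conditions, not performance under every demographic history.

### What R²-screening does and does not separate

A point the synthetic experiments make unmistakable: positive-OOB-R²
screening is **not** a test for local adaptation — it is a test for
climate-predictability of dosage. Under strong neutral structure
(F = 0.1) with ~20 individuals per population, every population's
climate vector is unique, population frequencies differ by design
(between-population dosage variance ≈ 2F/(2F+1) ≈ 17% of total), and a
forest can learn them from climate while pop-mates inform each
out-of-bag prediction; neutral OOB R² centres near +0.1 and essentially
all neutral SNPs pass the screen, the same as adaptive ones. Under
weak structure matching the motivating study (F = 0.02, ~7 individuals
per population, 281 populations) the neutral signal drops below the
overfitting penalty of the forest and neutral retention collapses to
~0% while planted clines are retained at ~100% — reproducing the
strong retention contrast reported for real candidate vs intergenic
SNP sets. Both regimes are recomputed by `scripts/acceptance.py`.
Users applying the pipeline to strongly structured species should not
read the retained fraction as an adaptive-SNP count.

## Numerical conventions

- MAF is computed from exact minor-allele counts, min(c, 2n−c)/2n, so
  the strict > 0.05 filter is immune to floating-point cancellation
  (1 − 190/200 > 0.05 in double arithmetic).
- Conservation identities are asserted at relative 1e−9; PCA
  reconstruction at relative 1e−8; turnover/tally oracle equality at
  1e−12 absolute.
- Importance ranking breaks ties alphabetically by variable name.
- Stage seeds derive from one master seed via SHA-256 substreams;
  per-SNP forest seeds via a SeedSequence; all below 2³¹.

## Problem sizes

The default test and acceptance runs use desk-scale landscapes chosen
to keep full suites in minutes while preserving the study's design
ratios: screening at the full 2 200-SNP × 1 000-individual design,
driver-recovery at 30 SNPs × 500 individuals × 20 replicates, rasters
of 10⁴ cells with PAM subsamples of 2 000–4 000 cells. Real
applications (3 × 10⁴ SNPs, ~10⁶ raster cells) run the identical code
paths; fitting cost scales linearly in SNPs and the transformation
linearly in cells.

## Known limitations

- The binned f(x) estimator and the W(k) normalization are this
  package's own conventions; absolute magnitudes are not directly
  comparable with other implementations, though rankings and shapes
  are.
- OOB R² screening conflates structure with adaptation under strong
  differentiation (above).
- PAM on a subsample can relabel near-boundary cells between seeds;
  zone boundaries are as uncertain as the underlying scores.
- Turnover functions are monotone summaries: they cannot represent
  non-monotone allelic turnover along a gradient.
- Rasters are plain-text ASCII grids in a local equal-area frame;
  reprojection and CRS arithmetic are out of scope.
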