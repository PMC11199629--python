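# Methods

This note documents the models, the synthetic-data regime, the numerical
choices, and the known limitations of `rseitools`.

## Harmonic reconstruction (HANTS)

The per-pixel model is a mean plus `nf` sine/cosine pairs at frequencies
`i / base_period` (defaults: nf = 1, base_period = 1 in the series' time
units, i.e. an annual fundamental on a fractional-year axis). Fitting is
ordinary least squares over the valid samples; a pixel with fewer than
2·nf + 1 valid samples is flagged unfittable and propagates nodata.
Classical one-sided outlier suppression (`outlier_mode` high/low/both) is
available: points deviating beyond `fit_tolerance` on the configured side
of the current fit are dropped and the fit repeated until stable, which
is the usual way to reject cloud-contaminated observations that bias
vegetation indices downward. The default is *no* suppression — plain
least squares — because that is the bare harmonic model; suppression is
an opt-in.

Stack fitting solves the per-pixel normal equations in a single batched
pass (validity acts as 0/1 weights), falling back to a per-pixel loop
only when outlier iteration is requested. Rank-deficient designs (all
valid samples at coincident phases) are solved by pseudo-inverse and the
affected pixels carry whatever the minimum-norm solution gives; with
≥ 2·nf + 1 distinct sample times this does not occur.

Accuracy statistics use the standard Pearson correlation and the root
mean squared pairwise difference. Some printed formulations of these
quantities circulating in the applied literature are typographically
inconsistent (an asymmetric correlation denominator; a mean inside the
squared RMSE term); the standard definitions are used, since
Taylor-diagram geometry (R, STD, RMSE) requires them.

Whether to fit one harmonic model across the whole multi-year record or
one per growing season is genuinely open. The library default
(`fit_stack`) is the full record; the *pipeline* default is per-year
(`hants_mode: per_year`), because a purely periodic full-record
reconstruction makes every year's growing-season composite identical and
would erase the interannual signal that the trend and breakpoint stages
analyze. Full-record mode remains available (`hants_mode: full`).

## RSEI construction

Per year, the pipeline median-composites the reconstructed NDVI, TCW,
NDBSI and LST over the May–October window, masks water where the MNDWI
composite exceeds a threshold (default 0.0 — conventional MNDWI usage;
the threshold is configurable), min-max normalizes each index over the
unmasked domain, and computes PC1 of the 4×4 covariance matrix of pixel
vectors. PCA is on the covariance of min-max-normalized indices rather
than the correlation matrix: normalization already removes scale, and
this keeps the normalize-then-PCA sequence explicit. A z-score
alternative (`standardize="zscore"`) exists because "normalized and
standardized" is ambiguous in parts of the literature; min-max is the
default.

The PC1 score is min-max rescaled to [0, 1] *before* orientation so that
the 1 − PC1 flip stays in [0, 1] and composes cleanly with the final
rescale. Orientation: both NDVI and TCW loadings positive → keep PC1;
both negative → 1 − PC1; mixed signs (undefined in the usual two-branch
rule) → the sign of (NDVI + TCW − NDBSI − LST loadings) decides, with a
RuntimeWarning, preserving the ecological direction (greenness/wetness
up, dryness/heat down). The final RSEI is invariant to the eigensolver's
arbitrary sign, which a dedicated test exercises by negating the
eigenvector.

Classification uses left-closed bins [0,0.2), [0.2,0.4), [0.4,0.6),
[0.6,0.8), [0.8,1]; 0.2 is "fair", 1.0 is "excellent". The annual
summary table rounds half-even to two decimals so table comparisons are
reproducible.

## Trend analysis

`sen_slope` defaults to the median of all pairwise slopes (the estimator
the method's name refers to); the arithmetic-mean aggregate is selectable
as `estimator="mean"` because a printed variant of the formula uses the
mean. The Mann–Kendall statistic S sums the signs of all pairwise
differences; the variance uses the tie-group correction
`VAR(S) = [n(n−1)(2n+5) − Σ q_k(q_k−1)(2q_k+5)]/18`; Z applies the
standard continuity correction `(S−1)/√VAR` for S > 0 and `(S+1)/√VAR`
for S < 0 (a printed source uses S−1 in both nonzero branches; the
standard form is implemented). The tie threshold ε defaults to 0 (exact
ties). Trend classes use |Z| cutoffs 1.96 and 2.58 (95% / 99% normal
quantiles); the underlying study never printed its class thresholds, so
these conventional values are the default and are configurable.

Breakpoint search is exhaustive over all placements of k breakpoints
with every segment ≥ `min_seg` (default 3) points; each segment is an
independent OLS line (segments are *not* constrained to join at the
breaks — the piecewise plots this mirrors show independent segments),
and the objective is `J = Σ_segments SSR/(2 m_seg)`. Ties break toward
the earliest placement; a `degenerate` flag is raised when no split
improves on a single line beyond `1e-12`. Exhaustive search at the
intended scale (n = 21, k = 3, ≈ 200 admissible placements) costs
milliseconds; no dynamic programming is needed.

## Spatial autocorrelation

Fishnet sampling takes cell-centered lattice points at a configurable
spacing. Weights default to queen contiguity on the fishnet lattice,
row-standardized — the de facto standard for lattice LISA maps; rook and
k-nearest (deterministic tie-break by point id) are available. Global
Moran's I is the standard `(m/S0)·ΣΣ W z_i z_j / Σ z_i²`; a printed
variant with the weight inside the denominator is available behind
`variant="as_printed"`, and both are tested against their own
double-loop oracles. The global permutation pseudo-p is one-sided for
positive autocorrelation by default (uniform under the null, which the
calibration test checks by KS).

Local Moran follows `I_i = z_i · Σ_j W_ij z_j / Σ z_i²`. LISA
significance uses conditional permutation (each point's own value fixed,
neighbor values drawn from the rest, with a shared permutation-index
table across points — the classic shortcut); the pseudo-p is the
*two-sided* `2·(min(#above, #below)+1)/(n_perm+1)` capped at 1, chosen so
the significance rate under an i.i.d. null stays near α rather than 2α.
Defaults: 999 permutations, α = 0.05, no multiple-testing correction
(matching common LISA practice); an FDR step can be layered on the
returned p-values by the caller.

## Geodetector

q = 1 − SSW/SST with *population* (1/N_h) variances, which makes the
variance-decomposition identity exact and q invariant under affine
transforms of the response. Continuous drivers are binned by quantiles
with k = 5 by default (configurable per call; equal-interval and exact
Fisher–Jenks natural breaks are provided, the latter by O(n²k) dynamic
programming). Significance defaults to a permutation test (response
shuffled over samples, seeded); the noncentral-F transformation is
available as `p_method="ncf"`. Interaction categories compare
q(X1∩X2) — computed on the co-occurrence strata — against min, max and
sum of the single-factor q values; "independent" (an exact equality in
the rule table) is granted within 1e-9. Because the co-occurrence
stratification refines both factors, q(X1∩X2) ≥ max(q1, q2) always holds
on shared samples; the two weakening categories are reachable only
through the classification rule itself, which the tests exercise on
constructed q triples.

A caveat the tests respect: the permutation test assumes exchangeable
samples. Spatially smooth response fields violate this and inflate
significance, so calibration checks use i.i.d. responses, and practical
runs on smooth fields should read p-values as descriptive.

## The synthetic scene

The generator emulates a plateau study region observed by Landsat-class
sensors over May–October windows:

- **Land cover**: a smoothed Gaussian random field thresholded at the
  cumulative class-fraction quantiles gives spatially contiguous patches
  (needed by the fishnet/LISA stages). Default composition: forest 50%,
  cropland 20%, grassland 10%, shrub 8%, impervious 5%, water 7% — a
  forest-dominated mix in the spirit of the region this emulates.
- **Signal**: per class and index, value(t) = mean + amplitude·cos(2πt −
  φ) + slope·year + noise, on a fractional-year time axis with
  `obs_per_season` dates per window (default 12 — the order of usable
  cloud-screened Landsat scenes per season). With zero noise, zero gaps
  and zero trend the stack is *exactly* an nf = 1 harmonic per pixel,
  which the exact-recovery tests rely on; trends and breakpoints are
  planted explicitly where a test or demo needs them.
- **Noise** (per-index SD): NDVI 0.03, TCW 0.008, NDBSI 0.008, LST 1.5 K
  — matched to the accuracy regime reported for reconstructed Landsat
  index series (wetness/dryness composites very clean, greenness
  noisier, LST about 1.5 K).
- **Gaps**: i.i.d. per (pixel, time) with default fraction 0.3 (cloud
  losses in a wet growing season), or contiguous "cloud blob" masks
  (`gap_mode="blob"`).
- **Quality surface**: one standardized smooth field modulates the
  within-class index means with the ecological signs (up for NDVI/TCW,
  down for NDBSI/LST), giving RSEI its spatial structure and a ground
  truth for rank-correlation tests.
- **Drivers**: continuous drivers are built as `effect·quality +
  √(1−effect²)·independent smooth field`, mapped to plausible physical
  units (temperature ≈ 15–24 °C, precipitation ≈ 790–1000 mm, altitude ≈
  1500–3100 m); class-ratio drivers are moving-window fractions of the
  land-cover grid. Default effects (altitude +0.6, temperature −0.4,
  precipitation +0.3, slope +0.3, aspect 0) encode the
  mountains-better/valleys-worse pattern.
- **Epoch change**: a second land-cover epoch converts configured
  fractions of source classes (default: cropland→impervious 5%,
  grassland→forest 5%, cropland→forest 3%), emulating urban expansion
  plus afforestation for the transition-matrix stage.

What the generator does *not* emulate: sensor spectral response or
cross-sensor differences, atmospheric effects, geolocation error,
SLC-off striping, or non-stationary phenology (phase is constant per
class). Passing tests therefore demonstrate correctness of the
*algorithms* under a controlled signal model, not robustness to every
artifact of real archives.

## Reproducibility and scale

All randomness flows from named, seeded generators; the pipeline derives
per-stage seeds from the global seed by hashing the stage name, so stages
are independently reproducible and a rerun with the same config produces
byte-identical CSV/JSON outputs (the manifest records parameters and
output hashes). Demo-scale defaults (32×32 pixels, 5 years, 99–199
permutations) keep a full run under a few seconds; simulation-based
calibration checks use 10,000 replicates for the Mann–Kendall null, 500
for detection power, and 100 for breakpoint recovery — sizes chosen so
Monte-Carlo error is small against the asserted bands.

## Known limitations

- LST enters as a data product; no thermal-band inversion is performed.
- The tasseled-cap wetness coefficient table is transcribed from the
  standard per-sensor derivations and is deliberately injectable; tests
  never depend on the transcription.
- No seasonal Mann–Kendall variant and no prewhitening: serial
  correlation in annual series will inflate MK significance.
- Global Moran's I is not guaranteed to lie in [−1, 1] for arbitrary
  weights; the empirical checks cover row-standardized lattice weights
  only.
- The geodetector's risk-area and ecological detectors are out of scope;
  only the factor and interaction detectors are implemented.
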