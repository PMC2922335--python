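# Methods

`nichecast` implements a climate-envelope forecasting pipeline for
presence-only species data and exercises it end-to-end on synthetic
landscapes where the true species–climate response is known. This note
records the models, the defaults and why they are what they are, the
numerical choices, and what the synthetic experiments do and do not
demonstrate.

## The maximum-entropy niche model

Given presence cells `x_1..x_m` and a background sample `B` of cells, the
model is a Gibbs distribution over `B`,

    raw(x) = exp(Σ_j λ_j f_j(x)) / Z,   Z = Σ_{y∈B} exp(Σ_j λ_j f_j(y)),

with weights chosen to maximize the L1-penalized presence log-likelihood

    (1/m) Σ_i Σ_j λ_j f_j(x_i) − log Z − Σ_j β_j |λ_j|.

This is equivalent to finding the minimum-relative-entropy distribution on
the background whose feature expectations match the presence means to
within per-feature boxes of half-width `β_j`; with all `β_j = 0` the
expectations match exactly (moment matching), and with no active
constraints the distribution is uniform over the background.

**Features.** Covariates expand into linear, quadratic, product, hinge
(forward and reverse, 8 evenly spaced interior knots per layer by default)
and threshold (8 knots) classes, each min–max scaled to [0, 1] on the
background. Which classes are active follows the presence-count
"auto-features" convention: fewer than 10 presences → linear only; ≥ 10
adds quadratic; ≥ 15 adds hinge; ≥ 80 adds product and threshold.
Features constant on the background are dropped with a warning.

**Regularization.** `β_j = c · β_class(m) · s_j / √m`, where `β_class(m)`
interpolates the per-class default tables on the presence count `m`, `s_j`
is the feature's standard deviation over the presences (background as a
fallback for degenerate features), and `c` is a single exposed global
multiplier (default 1.0). The tables are the conventional defaults of the
reference implementation; nothing in the synthetic experiments is
sensitive to their exact values.

**Optimizer.** Cyclic coordinate descent: each coordinate takes a
prox-Newton step (gradient = presence mean − model expectation, curvature
= model variance of the feature) followed by soft-thresholding against
`β_j`, with step-halving against the true penalized objective as a
safeguard. Convergence is declared when a full sweep improves the
penalized log-likelihood by less than `tol` (default 1e-6; the exactness
tests use 1e-12, which drives moment-matching error below 1e-6). The
default sweep cap is 500; non-convergence warns and returns the final
iterate by default (raising, with the best iterate attached, is available)
so that large replicate ensembles degrade gracefully rather than abort.

**Output scales.** `raw` is normalized over the training background and
that normalizer is reused when projecting, so raw values stay comparable
across scenario stacks. `cumulative(x) = 100 · Σ{raw(y) : raw(y) ≤
raw(x), y ∈ B} / Σ raw(y)` with inclusive ties — the top background cell
is exactly 100. `logistic(x) = r·e^H / (1 + r·e^H)` with `H` the entropy
of the fitted raw distribution; the default prevalence assumption implicit
in this transform is not altered. Projection clamps covariates to their
training (background) ranges by default; the flag is exposed.

## Evaluation

AUC is the Mann–Whitney probability that a presence outscores a background
point (ties 0.5), computed from training presences against the training
background — a single training AUC per species, no held-out split. It is
invariant under any monotone output transform.

The null-model test draws `n` points without replacement from the pooled
target-group background, fits the identical pipeline treating them as
presences, and repeats to build a null AUC distribution; a species' model
is significant only if its AUC strictly exceeds the empirical 95th
percentile of the null built at the size closest to its presence count
(ties to the larger size — configured sizes default to 50/205/405/695).
Because small draws overfit upward, null mean AUC decreases toward 0.5 as
the draw size grows; this trend is asserted as a test. Calibration is
checked by a type-I experiment: pseudo-species drawn from the pool itself
must be rejected at about the nominal 5% rate.

## Ranges, change and richness

Two binarization rules: **strict** — cumulative ≥ 10, with the inclusive
comparison (the reference convention; the boundary form is not otherwise
determined); **liberal** — score at least the minimum training-presence
score, which is scale-free and guarantees every training presence is
predicted suitable. Whenever the minimum training presence falls below
cumulative 10, the liberal range nests the strict one; this conditional
invariant is evaluated per fit, not assumed.

Projected maps (current and future alike — both are clipped, the more
conservative reading) are intersected with the documented range dilated by
a 10 km dispersal buffer. Buffering marks every cell whose center lies
within the distance (great-circle, via chordal nearest-neighbour search on
the sphere, which is exact for a distance cutoff) of a documented-range
cell center. Percent change is `100 · (current − future) / current` on
suitable-cell counts (positive = loss, never above 100); area is an
unweighted cell count on the fixed-cell-size WGS84 grid, with a
cosine-latitude-weighted variant available for sensitivity checks.
Percent overlap against the documented range uses the documented range as
the denominator ("how much of the documented range is captured"); the
modeled-range denominator is exposed as an option. Range centroid
latitude is the unweighted mean latitude of suitable cell centers.

Richness maps are cell-wise sums of binary ranges (species complexes
count as single modeled units), so total richness equals the sum of
species areas exactly. Two richness surfaces are compared by a two-sided
paired t-test at 250 cells (default) sampled uniformly without
replacement over the analysis frame (the full grid unless a frame mask is
given); identical surfaces yield a zero-variance difference and are
reported as degenerate rather than as a number.

## The factorial scenario analysis

Per species the scenario grid crosses 2 GCMs × 2 emissions levels × 2
thresholds (8 rows per species per year); years are analysed separately.
The response is √max(percent loss, 0) — gains are clamped to zero and the
clamped count logged, since the root of a negative loss is undefined; a
signed-root alternative is exposed. The linear model contains the
intercept, 5 main effects (3 sum-coded factors + 2 untransformed,
uncentered continuous covariates: current range size and centroid
latitude) and all 10 two-way and 10 three-way interactions, 26 parameters
in all; F tests use partial (Type III) sums of squares, with sequential SS
behind a flag. With 35 units × 8 scenarios this leaves 280 − 26 = 254
error degrees of freedom. Rank-deficient designs (including single-level
factors, which the formula machinery would otherwise silently drop) are
rejected with the aliased terms named. Centering the covariates changes
interaction interpretation, not the error df, and is exposed as an option.

## The synthetic landscape

Covariate stacks emulate bioclim-style layers: 11 layers by default (6
temperature-like, 5 precipitation-like) on a regular WGS84 grid of
0.0083° cells. Independent Gaussian white-noise fields are smoothed to an
autocorrelation range of 10 cells, standardized, and mixed through the
matrix square root of a target correlation (default: 0.7 within the
temperature block, 0.5 within precipitation, 0.2 across — moderately
collinear, as real bioclim subsets are). Temperature-like layers then
receive a monotone north-to-south warming gradient (default amplitude 2
layer standard deviations). All units are layer standard deviations; no
physical units are claimed.

Virtual species are logistic in the covariates: a concave quadratic
response to the first temperature layer with the optimum spread across
the thermal gradient (so range centroids span the latitude range), niche
widths of 0.2–0.4 layer-sd, peak log-odds 1–2, and a weak secondary
linear response to one other layer. These widths give prevalences of
roughly 0.1–0.4 — the restricted, climate-tracking ranges characteristic
of montane ectotherms; near-ubiquitous species would leave the ranking of
cells essentially unidentifiable from presence data and are not what the
pipeline is for. The "true range" is suitability ≥ 0.5.

Occurrences are drawn with probability ∝ suitability × an optional
collection-bias surface (default uniform; a few-foci museum-effort
surface is provided), snapped to cell centers, duplicates collapsed for
fitting; sets used for modelling must exceed 30 points. The pooled
target-group background is the cell-deduplicated union of all species'
points, subsampled to a cap (default 4215) when larger; it is the single
background for every fit. Documented-range stand-ins dilate the true
range onto coarse blocks (default 5×5 cells), emulating county-level
over-coverage; they are supersets of the truth by construction.

Future scenarios are additive offsets: warming of 0.5/1.0/1.5 layer-sd at
the three horizons, scaled by emissions level (A2a ×1.3, B2a ×0.8) and
circulation model (CGCM3 ×1.15, HADCM3 ×0.9), with precipitation-like
layers drying at half the warming magnitude. The deltas are spatially
uniform — real downscaled anomaly surfaces are not, and no GCM physics is
simulated.

## What the synthetic experiments show — and what they don't

Passing the recovery tests shows the estimator, thresholding, buffering
and change arithmetic are internally correct and that the pipeline
recovers a known quadratic climate response from unbiased samples
(Spearman ≥ 0.9 at 200 presences). Loss fidelity under uniform warming is
judged like for like: the reference applies the identical threshold rule
to the *true* suitability surface, so the comparison measures estimation
error rather than threshold convention, and it is asserted on the
community mean (within 10 percentage points), the aggregate the study
reports. Single-species loss estimates are intrinsically noisier: the
minimum-training-presence cutoff is an extreme order statistic of 200
draws, and at this sample size individual species' loss errors of ±15
points occur even when rank recovery exceeds 0.9 — a real property of
threshold-based change estimates worth remembering when reading
per-species tables. The strict cumulative-10 rule cuts at a lower density
level where relative estimation noise is larger still; the fidelity check
therefore uses the minimum-training-presence rule, which tracks the
occupied-range boundary. None of this
validates behaviour on real data, where sampling bias, covariate error,
non-equilibrium ranges and biotic interactions all violate the
generator's assumptions; the target-group background is a bias *proxy*,
not a claim about any particular data source.

## Problem sizes and numerical notes

Default study: 100×100 cells, 11 layers, 35 species, 200 presences each,
background cap 4215, 1000 null replicates, 250 comparison points. The
bundled acceptance script runs a reduced instance chosen to exercise every
stage at desk scale: a 60×60, 4-layer landscape with linear+quadratic
features for the 35-unit study and 100-replicate nulls, and a 100-trial
type-I experiment with fresh 100-replicate nulls per trial; the test
suite runs the calibration at 200 trials × 200 replicates. Degenerate
inputs are signalled, not silently handled: empty backgrounds, all-zero
sampling weights, zero current area (undefined loss), empty documented
range (undefined overlap), non-finite covariates, oversized null draws
and non-WGS84 sidecar projections all raise with a message naming the
problem. Every stochastic stage takes an explicit seed; a study config
derives per-stage seeds from one master seed via CRC-tagged seed
sequences, and re-running a config reproduces byte-identical CSVs.

## Known limitations

- Spatially uniform scenario deltas; no anomaly surfaces or GCM physics.
- No cross-validation, partial AUC, TSS/kappa, jackknife variable
  importance or response-curve machinery.
- No categorical covariates; no mechanistic dispersal; no land-cover
  masking; no vector geometry (all range operations are raster masks).
- The factorial GLM treats species as independent units (no random
  effects), and no multiplicity adjustment is applied across terms.
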