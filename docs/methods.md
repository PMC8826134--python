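# Methods

## The modelling problem

Large soaring raptors collide with wind-turbine blades when they fly within
the rotor-swept band, roughly the lowest 200 m above ground. Given GPS
telemetry with altitude and instantaneous ground speed, the pipeline models
the probability that a bird at a given location flies *below the critical
altitude* of 200 m above ground level (AGL), as a function of terrain, land
cover, geology, wind climate and food availability, and projects that
probability across a study region to delineate collision-risk hotspots.

The response is binary: label 1 if AGL < 200 m (strictly), 0 otherwise.
The classifier is a feedforward network with two hidden layers
(rectified-linear by default), an inverted-dropout layer between them, and
a single sigmoid output, trained by Adam on binary cross-entropy with early
stopping on validation AUC. The mapping stage converts fitted probabilities
into decision products: a bagged mean probability surface with a 95%
percentile interval, a binary critical-flight map thresholded to retain a
95% true-positive rate, and — combined with an externally supplied
occurrence-probability raster and 4-level potential-conflict raster — a
joint-probability map and a high-risk conflict map with area shares.

## Track cleaning

Raw fixes pass through ten ordered stages (see `lowflight.trackproc`):
completeness (altitude and speed both present), datum conversion
(ellipsoidal heights minus a geoid-undulation raster give sea-level
heights; AGL is sea-level height minus the terrain elevation of the
containing 25 m cell), a positional-quality cull (HDOP ≥ 10 removed when
HDOP is provided, otherwise position error ≥ 30 m), an AGL plausibility
window of −50 … 4000 m (inclusive at both ends; negative AGL arises from
combined GPS and terrain-model error near steep slopes), a
sunrise-to-sunset filter (geometric solar elevation ≥ 0, no refraction; the
solar position uses the NOAA series, accurate to a few minutes, which is
ample), a flight filter removing fixes that are simultaneously slow
(< 2 m s⁻¹) and low (< 100 m AGL) — perched birds — a study-region mask, an
eight-week post-fledging exclusion (exactly 56 days; the boundary instant
is retained), per-minute subsampling (the earliest fix of each bird-minute,
a deterministic choice), and finally a ≥ 100-fix minimum per bird.

Subsampling must run after all removal filters: running it earlier can let
a perched fix shadow a valid flight fix in the same minute (this order
sensitivity is tested). Every filter is idempotent and only removes rows;
the `CleaningReport` chains stage counts exactly.

When both HDOP and position error are present, HDOP governs. All
timestamps are UTC.

## Predictors and encoding

From a 25 m elevation model: slope and aspect by Horn's 3×3 weighted finite
differences (aspect encoded circularly as eastness = sin, northness = cos
of the downslope direction clockwise from north; flat cells get 0/0),
topographic position index (cell elevation minus the mean of its eight
neighbours, centre excluded) and slope unevenness (the same operator
applied to the slope band). Border cells and neighbourhoods touching
nodata are nodata. Wind speed at 100 m above ground arrives on a 100 m
grid and is resampled bilinearly to 25 m (a convex combination, so bounds
are preserved). Land cover (10 classes) and geology (4 classes) are
one-hot encoded; the 8 continuous variables are z-scored with mean/sd from
the *training split only*. The feature layout is a fixed contract:
10 land-cover indicators, 4 geology indicators, then eastness, northness,
slope, slope_unev, tpi, ibex, chamois, windspeed — 22 columns.

A Spearman collinearity screen over 10 000 random cells flags continuous
pairs with |r_s| ≥ 0.6 (none arise in the synthetic world; the maximum is
typically ≈ 0.5–0.6 between slope and its unevenness).

## Classifier

Defaults: 256 and 32 hidden units, dropout 0.4, Adam with learning rate
10⁻³, β₁ = 0.9, β₂ = 0.999, ε = 10⁻⁷, batch size 512 — the framework
defaults a practitioner would leave untouched. Probabilities are clipped
at 10⁻⁷ inside the loss. Early stopping: training halts once the
validation AUC has not strictly improved for more than `patience` (10)
consecutive epochs, and the best epoch's weights are restored. Weights are
initialized He-style (N(0, 2/fan_in)), biases zero, all seeded; training
is bit-reproducible on a platform. Analytic backpropagation is verified
against central finite differences to relative error < 10⁻⁵.

The hidden activation is not dictated by the architecture description;
rectified-linear is the standard choice and is configurable (`tanh`
available, and used in the gradient checks where smoothness helps).

The architecture grid search spans widths {16, 32, 64, 128, 256, 512} for
each hidden layer and dropout 0.2–0.7 in steps of 0.1 — 216 configurations
on one fixed 70/30 split. The 70/30 split is random over fixes (seeded);
bird-stratification was considered and rejected as the default because the
cross-validation designs below already probe across-bird transfer.

## Evaluation

AUC is the rank-based Mann–Whitney statistic with ties counted ½, checked
in the tests against exhaustive pair enumeration and an independent
library implementation.

Two cross-validation designs, both training for a fixed 20 epochs with no
early stopping (so no per-fold validation split is needed): leave-one-bird-
out (one model per individual) and spatial-block CV (square blocks tiling
the region's bounding box from its origin, partial edge blocks kept,
assigned to five folds by a seeded shuffled round-robin, balanced to within
one block). A variogram routine recommends a minimum block side: per
continuous band, an empirical semivariogram from pairs sampled with
log-uniform lags (capped at half the grid extent), a weighted
least-squares exponential fit γ(h) = c₀ + c₁(1 − e^(−h/a)) over 15
log-spaced lag bins, practical range 3a; the recommendation is the median
over bands. If the exponential explains essentially nothing beyond a
constant (or its sill share is < 5%), the band is treated as pure nugget
with range one cell. The exponential practical range of a Gaussian-shaped
field overshoots the direct 0.05-decorrelation lag by a factor of ~2–3;
the tests encode that bias explicitly.

Permutation importance permutes each variable group's columns jointly
(one-hot rows move intact) and reports the mean over 10 repetitions of the
relative AUC drop, 100·(AUC₀ − AUCₚ)/AUC₀; an absolute percentage-point
form is available, as is a headline grouping that merges eastness+northness
into "aspect" and ibex+chamois into "food". ICE curves evaluate each
observation's prediction as one focal variable sweeps a grid of n equally
spaced values on its natural scale (class codes for categorical
variables), normalized with the stored training statistics before
prediction; the PD curve is the exact column mean of the ICE matrix.

## Mapping

Bagging: 30 members, each trained on a seeded bootstrap resample of the
training split (same size, with replacement — about 63.2% unique rows per
resample) with early stopping on the shared validation split. The final
map is the cellwise mean; uncertainty is the cellwise empirical 2.5/97.5
percentile band (linear interpolation between order statistics; with 30
members the interval essentially spans the ensemble, which is why the
method is documented rather than hidden). The binarization threshold is
the largest score value whose true-positive rate on the selection data is
at least 95%; binarization uses ≥ so the achieved sensitivity matches the
selection TPR exactly. The threshold is selected on the full modelling
dataset (train + validation) by default, restrictable to either split.
The joint-probability map is the cellwise product of the low-flight and
occurrence maps; the high-risk map keeps the potential-conflict level
(1–4) where low flight is predicted and 0 elsewhere, with area shares as
cell counts × cell area over the region mask.

## The synthetic world

No public tracking data exist for this system, so `lowflight.synthgen`
builds a self-contained study system in planar metre coordinates:

- **Terrain**: Gaussian-filtered white noise rescaled to a 1500 m relief
  over a 200×200 grid of 25 m cells (5 km × 5 km), smoothing scale 500 m —
  Alpine-like local relief at desk scale.
- **Bands**: land cover (10 classes; quantile bins of an
  elevation-plus-noise field, so classes are spatially coherent), geology
  (4 classes), ibex and chamois occurrence (logistic transforms of
  elevation plus smooth noise; ibex is deliberately elevation-coupled so
  its effect is learnable), wind at 100 m resolution (smooth, ≥ 0, mean
  ≈ 5 m s⁻¹), a ±60 m smooth geoid-undulation field, and a region mask
  excluding an 8-cell margin (which also provides out-of-region cells).
- **Low-flight process**: at each fix cell the 22 encoded features
  (z-scored with map-wide statistics) enter a logistic model with a known
  coefficient vector. The default coefficients make slope the dominant
  driver (+1.3 per sd), with ibex (+0.8), windspeed (+0.6) and northness
  (−0.5) secondary, and rock/scree favoured over forest/water — the
  qualitative structure reported for Alpine soaring raptors. The default
  intercept (1.8) puts ≈ 74% of clean fixes below 200 m AGL, matching the
  share observed in the real telemetry. True AGL is drawn uniformly on
  [0, 200) m for label 1 and [200, 1500) m for label 0; reported altitude
  adds N(0, 10 m) vertical noise and is expressed in the bird's datum
  (sea-level or ellipsoidal, per device).
- **Schedules**: 40% of birds emit 1 Hz bursts of 30–60 s between short
  gaps; the rest emit one fix per 1–15 min; all base fixes fall in a
  09:30–15:30 UTC window over a summer season at 46.5° N, 8° E.
- **Contamination** (disjoint subsets per bird, so the cleaning audit is
  exact): night fixes 12%, perched fixes 8% (speed < 2 m s⁻¹, AGL
  5–60 m), poor quality 5% (HDOP 10–25 or error 30–120 m), pre-fledging
  3% (the bird's fledge instant is set 56 days before its (k+1)-th fix, so
  the cut removes exactly k fixes — synthetic fledge "dates" therefore
  carry a time of day), out-of-region 3%. Rates are fixed defaults; the
  three desk checks that require exact accounting set vertical noise to
  zero by design, since noise can move a fix across the AGL thresholds of
  a different stage.
- **Truth**: per-fix generating probabilities and labels, and a
  Monte-Carlo *achievable* AUC (labels redrawn from the true
  probabilities, 10 draws) against which trained models are compared.

What the generator does **not** emulate: home ranges or autocorrelated
movement (positions are independent draws over the region), geographic
coordinates and CRS handling, inter-bird heterogeneity in behaviour, and
real geodata artefacts (mixed resolutions, reprojection error, class
imbalance of Alpine land cover). Passing tests therefore demonstrate that
the machinery recovers a known generating process under realistic noise
and contamination — not that the ecological conclusions transfer to any
particular real landscape.

## Problem sizes and numerical choices

The study-scale runs used by the test suite and the acceptance script
generate 50 000 fixes (25 birds × 2000); cleaning and subsampling leave
≈ 21 000 modelling rows, on which the default 256/0.4/32 network trains in
a few seconds per run. Unit-level checks use 40–100 cell grids and
3–8 birds. The analysis drivers default to a reduced 8-point architecture
grid (`--full` restores all 216). Cross-validation checks run a 32/16
network at ≈ 5000 rows. Raster I/O is plain-text ESRI ASCII grid —
adequate for desk-scale grids and diff-friendly; all geometry is planar.

Degenerate inputs fail loudly: zero-variance continuous columns name the
column; single-class validation splits are rejected (held-out CV units
with a single class get an undefined test AUC and a warning, and are
excluded from the mean); non-finite gradients raise; points outside raster
coverage raise. Cells are half-open ([x, x+res) × top-down rows), so a
point on a shared edge belongs to the cell to its east/south.

## Known limitations

- The percentile interval from 30 bootstrap members is coarse; it brackets
  ensemble spread, not full posterior uncertainty.
- The variogram range estimator is biased upward for smoothly varying
  (Gaussian-autocorrelated) fields, as documented above; its output is a
  block-size recommendation, not an estimand of interest.
- The exact geodetic transform between ellipsoidal and sea-level heights
  is abstracted to an undulation raster.
- With a 5 km synthetic domain, spatial-block CV uses ~1 km blocks; the
  10 km default block side is meant for study-scale extents.
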