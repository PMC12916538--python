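# Methods

This note documents the models and procedures implemented in `hstrend`,
the choices made where the design was genuinely open, and what the
synthetic validation does and does not demonstrate.

## Pipeline overview

The package estimates, for each species, where habitat suitability has
been changing over a multi-year window, and summarizes those changes into
vulnerability statistics:

1. **Predictor screening** — candidate environmental predictors are
   checked for multicollinearity (VIF and pairwise Pearson r) and pruned.
2. **Annual niche models** — for every year, a presence/background
   maximum-entropy model is fitted in 10 replicates (70/30 train/test
   split); annual habitat suitability (HSI) is the replicate mean.
3. **Null-model calibration** — model performance (AUC) is compared with
   models fitted to randomly placed occurrence sets of the same size.
4. **Trend detection** — per grid cell, the Mann-Kendall test and Sen's
   slope are applied to the annual HSI series.
5. **Vulnerability summaries** — trend maps are masked to significant
   cells (p < 0.05, strict) inside the species' range; the proportion of
   masked cells with negative slope is the species' vulnerability metric;
   group-level statistics pool masked pixels across species and are
   compared with one-way ANOVA plus Tukey HSD.

## The maximum-entropy model

The model estimates the distribution `q` over background cells (the
centroids of all grid cells of the training region) maximizing entropy
subject to L1-regularized constraints tying expected features under `q`
to their empirical means over the presence cells. Equivalently it
maximizes the concave penalized log-likelihood

    L(λ) = mean_presence(λ·f) − log Σ_background exp(λ·f) − Σ_j β_j |λ_j|

Features are standardized linear and quadratic terms of each continuous
predictor (binary predictors enter linearly); standardization parameters
and feature clamp ranges come from the background only, so a model can be
projected onto cells outside its training region with features clamped to
the calibration range. The regularization weights are
`β_j = β_multiplier · s_j / √m`, with `s_j` the feature's standard
deviation over the `m` presences (floored at 1e-6).

This is a deliberately simplified member of the MaxEnt family: no hinge,
threshold or product features, a single β rule rather than the per-class
lookup tables of the canonical implementation, and logistic output
`s = e^H·r / (1 + e^H·r)` where `r = q·|B|` is the background-relative
rate and `H` the entropy of the fitted distribution. These choices keep
the model fully specified by the code while preserving its character — a
regularized Gibbs distribution contrasting presences with background.
All knobs (`β_multiplier`, replicate count, train fraction, output scale)
are exposed in configuration.

The L1 problem is solved exactly by splitting `λ = u − w` with
`u, w ≥ 0`, which turns the penalty into a smooth linear term over a
bound-constrained domain, handed to L-BFGS-B. Convergence is tight
enough that the KKT moment conditions hold to 1e-4: for every feature,
|E_q f − mean_presence f| ≤ β_j, with equality where λ_j is active. The
fit is deterministic given its inputs; replicate randomness comes only
from the named per-(species, year, replicate) RNG substreams used for
the 70/30 shuffles.

Train-set size is round-half-up of 0.7·n. AUC is the Mann-Whitney
statistic of presence scores against all background scores (presence
cells are not removed from the background), the standard
presence/background evaluation.

## Null models

Each species' AUC is calibrated against models fitted to occurrence sets
of equal size placed by complete spatial randomness — uniform draws of
distinct cells, i.e. a homogeneous Poisson point process conditioned on
n. The "Poisson distribution" of the classical recipe is read this way,
not as a Poisson-distributed sample size. Two decision surfaces are
exposed: the per-species 95th-percentile criterion (significant when the
empirical training AUC exceeds the 95th percentile of the null
distribution) and a pooled paired Wilcoxon signed-rank test across
species. The signed-rank test uses the normal approximation with
tie-corrected variance and a 0.5 continuity correction — adequate for
the n ≥ 5 pairs this pipeline produces, and within 0.08 of the exact
permutation p for n ≤ 12 (verified by enumeration in the test suite).

## Trend detection

Per cell, over the annual HSI values with years as integer offsets
0..T−1: the Mann-Kendall statistic `S = Σ_{i<j} sgn(x_j − x_i)` with the
tie-corrected variance `var_S = [n(n−1)(2n+5) − Σ_t t(t−1)(2t+5)]/18`,
continuity-corrected normal z, and two-sided p; and Sen's slope, the
median of all pairwise slopes. The normal approximation is standard for
series of the default length (T = 23); no exact small-n table is
provided, so T ≥ 10 is assumed. All-tied series get p = 1; cells with
fewer than 3 usable years are flagged missing. Implementations are
vectorized across cells and verified against exhaustive pairwise
enumeration (exactly for S, var_S and the slope; to 1e-12 for p) and
against a type-I calibration: under i.i.d. noise the p < 0.05 rate over
5000 cells is binomially consistent with 0.05.

## Masking and vulnerability summaries

A species' trend map is masked twice: keep cells with p < α (strict
inequality at the boundary) and inside the species' range. Because the
source analyses never define "distribution range" operationally, three
range constructions are provided — convex hull of occurrence centroids
(default), Chebyshev buffer around occurrences, and occupied cells only —
and none is asserted as canonical. Collinear occurrence geometries fall
back from hull to buffer with a warning.

Counts satisfy `n_neg + n_pos + n_zero = n_significant` by construction
(asserted on every summary). An exactly zero slope on a significant cell
is counted in `n_zero` and excluded from both proportions: zeros are
measure-zero in theory but must be handled deterministically. Proportions
use significant-and-in-range cells as the denominator, so positive and
negative shares sum to 1 when there are no zeros; the range-cell count is
also reported. Group aggregation defaults to pooled pixel counts (a cell
counts once per species covering it); an unweighted mean-of-species
variant is provided. Group comparison is one-way ANOVA on per-species
negative proportions followed by Tukey HSD (studentized-range adjusted).

## Collinearity screening

VIF is 1/(1−R²) of each predictor regressed (with intercept) on the
others, over valid-cell values pooled across all years (a per-cell
multi-year-mean pooling is available by option). The elimination order is
unspecified in the source analyses, so a deterministic greedy rule is
fixed: repeatedly drop the max-VIF predictor while any VIF ≥ 4, then
break remaining pairs with |r| ≥ 0.75 by dropping the member with the
higher mean |r| to everything still retained; ties resolve by
candidate-list order. Zero-variance predictors are dropped as
"degenerate". The full report (retained set, drop reasons and
statistics, final VIFs, correlation matrix) is emitted.

## Synthetic landscapes and virtual species

The generator provides every downstream stage with known ground truth.
Its defaults mirror the scale of the target study system: a 30 × 29
lattice (870 valid cells — also the background-point count), 23 annual
layers, six predictors (five continuous, one binary annual-burn layer),
25 virtual species in five pseudo-taxonomic groups, 30 presence cells
per species, and a 15-record minimum.

Continuous predictors follow `value(cell, t) = B(cell) + τ(cell)·t + ε`
with `B` a moving-average-smoothed white-noise field (radius 3 cells,
standardized within each regional band so offsets are exact), `τ`
piecewise-constant over five equal column bands, and
`ε ~ N(0, noise_sd)` i.i.d. Virtual species have product-Gaussian
responses `S* = exp(−Σ_p (v_p − μ_p)²/(2σ_p²))`; presences are drawn
without replacement proportionally to the suitability of the
time-averaged predictors. Ground truth per cell is the sign of the OLS
slope of the noise-free suitability series.

The trending predictor's landscape is engineered so that recovery of the
imposed trends through the full pipeline is actually attainable — a
non-trivial requirement, because a compiled (time-pooled) occurrence set
combined with annually refit models lets the estimated niche *track* a
drifting environment, erasing or inverting per-cell suitability trends.
Three design elements address this:

- **Offsetting band pairs.** Each species cohort occupies a pair of
  bands with equal and opposite drifts (±0.04 units/year), so the
  presence sample's environmental mean is stationary and the annually
  refit niche stays anchored. "Declining" species occupy bands whose
  values start one unit from the niche centre and drift away;
  "improving" species occupy bands that are the exact time reversal
  (starting 1.88 units away and drifting toward the centre).
- **Attractor strips.** The top and bottom rows of each trending band
  sit at the niche-crossing value (∓0.44, half the total drift), giving
  the sampler value-symmetric cells whose pooled distribution is
  invariant under the drift — this keeps the *width* of the presence
  sample stationary too, which matters because the quadratic features
  track it.
- **An unsuitable ridge.** The central band is offset far (3 units) from
  every species' niche centre, so it attracts no presences and no
  species' range spans both landscape halves. Without it, statically
  suitable cells with zero true trend enter ranges and accumulate
  spurious significant trends from residual model drift — the
  Mann-Kendall test is scale-free, so even tiny monotone drifts in
  fitted model parameters register as significant at far-from-niche
  cells.

A static west-east gradient predictor (plus weak smoothed noise)
localizes each cohort to its band pair (response width 0.2); interannual
noise on the trending predictor (sd 0.3) keeps sub-signal model drift
below the trend-detection threshold. Species niche centres get small
reproducible jitter (sd 0.1); traits and IUCN codes are drawn randomly
per species from fixed vocabularies, except that the habitat label marks
the declining cohort so group-level contrasts are recoverable by
trait-based grouping.

What passing the recovery tests shows: the pipeline's trend maps and
vulnerability proportions faithfully reflect true suitability dynamics
*when the occupied environmental distribution is stationary*. What it
does not show: behaviour under niche drift (occurrence compilations whose
environment trends in one direction), under strong sampling bias, or
with the spectral/QA artifacts of real remote-sensing series — none of
which the generator emulates.

## Problem sizes used in validation

The test suite uses the default fixture (870 cells, 23 years, 25
species) for the single recovery and calibration runs, a reduced
five-species community for the 20-replicate cohort-contrast check, and
reduced null-model settings (5 years, 5 replicates, 39 nulls) for the
repeated significance-calibration check; the headline null-model
calibration itself runs at full size (100 nulls, 23 years, 10
replicates). These sizes were chosen so the entire validation runs on a
single CPU in well under half an hour while keeping every statistical
check at a meaningful resolution.

## Numerical choices

- Nodata sentinel −9999.0 (configurable); rasters interchange as
  plain-text ESRI ASCII grids, one file per layer plus a JSON manifest.
- Cell indexing is 0-based row-major with row 0 north; coordinates are
  cell centroids; points on shared cell edges belong to the cell
  right/below (floor-division snap).
- L-BFGS-B with ftol 1e-9 and projected-gradient tolerance 1e-6; on
  iteration exhaustion the best iterate is returned with a warning flag.
- Sen slope of an even pair count is the mean of the central pair
  (ordinary median).
- Group-slope SD uses the sample (ddof = 1) convention and is undefined
  for fewer than two values.
- Quantiles for the 95th-percentile null criterion use NumPy's default
  linear interpolation; significance is strict (>).

## Known limitations

- No autocorrelation-corrected Mann-Kendall variant (Hamed-Rao) — with
  10-replicate averaging the HSI year noise is close to independent by
  construction in the synthetic setting, but real HSI series may be
  serially correlated.
- The logistic output saturates near 1 for strongly concentrated models,
  compressing trends at the best-matched cells (they typically fail the
  significance mask rather than mislead).
- Convex-hull ranges over-cover concave distributions; the buffer
  method is the conservative alternative.
- CRS handling, reprojection and true GeoTIFF I/O are out of scope; the
  grid is a plain rectangular lattice in map units.
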