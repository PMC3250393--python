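# Methods

This note documents the models, parameter choices and known limitations
behind canopyfuse, in the order data flows through the package.

## Synthetic scene (`canopyfuse.scene`)

**Terrain.** A radial quadratic basin (low center, high rim) blended with
low-frequency Gaussian-smoothed noise (default weight 0.25, smoothing
length 8 cells at 5 m resolution), then rescaled so the minimum and
maximum equal the configured elevation range exactly (default
220–1,015 m). The rescaling makes the range a hard contract rather than a
statistical outcome.

**Stand.** An inhomogeneous Poisson process realized by thinning: the
local density multiplier is 1 + 0.4·p_conifer(z), normalized to mean 1 so
`stem_density` (default 500 stems/ha) is the landscape average. Conifer
probability rises logistically with elevation (midpoint 620 m, width
90 m). Heights are type-specific normals (conifer 12 ± 2.5 m, deciduous
20 ± 4 m) truncated to [3, 35] m; crown radii follow the linear allometry
r = 0.5 + 0.12·h (+ N(0, 0.25 m)), truncated at 0.3 m — plausible
temperate-forest values, fully configurable. Crown overlap is not
rejected; overlapping crowns are realistic and harmless downstream.

**Plots.** Circular 50 m-radius count plots (0.785 ha) on a north–south
transect grid; the aggregation pixel is the 88.8 m square (0.789 ha)
centered on each plot. Grid spacing is configurable; no fidelity to any
particular real transect spacing is claimed.

**Prevalence.** Habitat covariates (elevation, deciduous stem fraction,
stem density, mean height, crown-area cover in the 5–15 m and 15–25 m
strata) are computed directly from the stem map per plot, z-scored over
the plot set so species coefficients are scale-free, and yearly detection
is Bernoulli(expit(β₀ + β·z)); prevalence is Binomial(years, p) with 9
years by default. The eight default species archetypes encode
conifer/high-elevation vs deciduous/low-elevation preferences mirroring
the classic songbird guilds of northern hardwood forests. Within-season
visits, territoriality and residual spatial autocorrelation are *not*
modeled: detection-years are conditionally independent given habitat.

## Sensor simulators (`canopyfuse.sensors`)

Mechanistic but deliberately simple forward models — no radiative
transfer, no SAR scattering physics, no atmosphere, no geolocation error.
Crown envelopes are vertical paraboloids from the tree top down to 60 %
(conifer) or 40 % (deciduous) of height, giving type-distinct profiles.

* **Discrete-return lidar:** Poisson pulses (default 1/m²); first return
  at the highest crown envelope over the pulse (ground if open); the last
  return reaches the ground with probability 0.6ⁿ for n covering crowns,
  otherwise stops at the lowest crown base; an extra mid-crown return
  occurs with probability 0.25. Vertical noise N(0, 0.1 m).
* **Waveform lidar:** 25 m footprints, 0.3 m bins spanning mean ground
  −5 m to +45 m. Each tree contributes a Gaussian lobe truncated to its
  crown depth with energy proportional to its in-footprint crown area
  (exact circle–circle overlap); exposed ground contributes a truncated
  Gaussian whose width combines a 0.5 m pulse width with in-footprint
  terrain relief. Additive Gaussian noise (mean 0.3, sd 0.1 in amplitude
  units where reflectance-per-m² is 1) travels with the waveform so
  detection thresholds are self-contained. The 0.3 m bin width is an
  implementation default, not an instrument value.
* **Radar:** per 5 m pixel, a biomass proxy B = Σ 0.5·Ca·H / pixel-area;
  mean linear power a·(1 − e^(−B/B_sat)) + floor per polarization
  (a = 0.25/0.20/0.08, floor = 0.010/0.010/0.002 for HH/VV/HV,
  B_sat = 10), multiplied by gamma speckle with 4 looks, output in dB.
  The HV channel is most biomass-sensitive, and the saturation constant
  places typical mature stands near the onset of saturation.
* **Multispectral:** per 30 m pixel, target NDVI mixes canopy NDVI with
  soil NDVI (0.12) by crown cover; leaf-on canopy NDVI is 0.85 for both
  types, leaf-off drops to 0.25 for deciduous and 0.75 for conifer, so
  seasonal NDVI change isolates deciduousness. Red/NIR are solved from
  target NDVI at fixed brightness 0.45, noised (sd 0.01) and clipped to
  [0, 1].

## Discrete-return products (`canopyfuse.drl`)

Gridding uses max-per-cell for first returns (DSM) and min-per-cell for
last returns (DEM) at 0.5 m, with empty cells filled from the nearest
populated cell — the standard bias-minimizing choice at ≥1 pulse/m².
CHM = DSM − DEM clipped at 0. Tree detection is adaptive local-maxima
filtering: the circular search radius at each cell comes from a
least-squares crown-radius-on-height line calibrated on (height, radius)
pairs (in the pipeline, a random sample of true stems stands in for field
calibration trees), clipped to the calibration radius range and floored
at one cell. A cell is a top iff it strictly exceeds every other cell in
its window; equal-valued ties resolve to the first cell in row-major scan
order, so plateaus count once and output is deterministic. Crown radius
is taken from the calibrated model rather than CHM profile walking —
simpler and deterministic. The minimum tree height is 2 m (excludes
shrubs and surface noise). Detection recovers dominant/co-dominant crowns
only; understory stems below taller neighbors are invisible by design, so
detected stem density underestimates total stand density.

## Waveform products (`canopyfuse.waveform`)

Canopy top is the highest bin exceeding noise_mean + k·noise_sd with
k = 4 by default (the threshold multiplier is exposed; no canonical value
exists). Waveforms are ground-corrected by subtracting the mean DRL-DEM
elevation within the footprint — the point cloud finds ground more
reliably, while the waveform's own canopy-top detection is kept. RH
quantiles subtract the noise floor, clip negatives, accumulate energy
from the lowest bin upward over bins at or below the detected top, and
interpolate linearly within the crossing bin; quantiles are clipped at
the canopy top so RH25 ≤ RH50 ≤ RH75 ≤ RH100 holds exactly. By default
the cumulative total includes ground energy (a switch excludes energy
below the 2 m split instead). Total cover is
E_canopy/(E_canopy + ρ·E_ground) with the canopy/ground split at 2 m (the
shrub-stratum boundary) and reflectance ratio ρ = 1 by default. The cover
profile uses 8 bins of 5 m from 0 to 40 m, with energy above 40 m added
to the top bin and the below-0 m ground term kept separate so bin
fractions plus the ground fraction conserve total signal energy; the
feature schema consumes the 7 bins up to 35 m (see below).

## Radar/optical products (`canopyfuse.surface`)

dB→power precedes filtering because ratios and gamma statistics are
defined on the linear scale. The 3×3 gamma-MAP filter classifies pixels
by local coefficient of variation (homogeneous → local mean; point
target → unchanged; otherwise the positive root of the MAP equation for a
gamma-distributed scene under gamma speckle, 4 looks by default, matching
the simulator); edges use truncated neighborhoods and degenerate MAP
solutions fall back to the local mean. Nine bands result: three powers,
three ratios, three normalized differences; any missing input pixel makes
every derived band missing there.

## Feature table (`canopyfuse.features`)

Raster metrics aggregate cells whose centers fall in the plot's 88.8 m
square; per-item records (detected trees, waveform footprints) aggregate
items whose centers fall inside — deterministic, edge-unambiguous.
Statistics are min/max/mean/sample-sd (n−1; a single item gives sd 0, not
missing). The 104-column schema is
radar 9×4 = 36, NDVI + NDVI-change ×(mean, sd) = 4, waveform-lidar
elevation ×(mean, sd) + RH25/50/75/100 ×4 + total cover ×4 + seven 5 m
cover bins (0–35 m) ×4 = 50, and DRL tree height/crown diameter/
height×diameter ×4 + stem density + crown-area-weighted height = 14. The
cover profile computes 8 bins but the schema takes the 7 below 35 m: that
is the only column accounting consistent with the 104 total, and the top
bin remains available outside the schema. Stem density and
crown-area-weighted height enter as plot scalars (they are not
within-plot distributions). Plot exclusion removes explicitly listed
plots plus any plot with a missing predictor, logging reasons; the join
validates one prevalence record per retained plot and species, in [0, 9].

## Fusion models (`canopyfuse.fusion`)

Tree induction delegates to scikit-learn's `DecisionTreeRegressor`;
bagging, OOB bookkeeping, pseudo-r², importance and quantiles are native.
Defaults: 800 trees, ⌊p/3⌋ candidate predictors per split, minimum leaf
size 5 (the regression default of the classic randomForest
implementation). Each tree trains on a with-replacement resample of size
n; the OOB prediction for observation i averages trees whose resample
omitted i (≈ e⁻¹ ≈ 37 % of trees), and extra trees are grown in the rare
case an observation is never out of bag.

*pseudo-r²* = 1 − MSE/Var(y) with **population variance** (n denominator)
for internal consistency between numerator and denominator (the mean
predictor then scores exactly 0); implementations using the sample
variance differ by < 0.3 % at n ≈ 370.

*Importance* is permutation-based: per tree, a predictor's values are
permuted within that tree's OOB set and the mean MSE increase over trees
is reported — the OOB operationalization of "error increase on removing a
predictor". Removal-plus-refit importance is a computationally different
object and is not implemented. Because the generator ties composition and
density to elevation, most habitat covariates have several correlated
sensor measurements; the one-signal recovery test therefore drives a
species by elevation, the single covariate with an unconfounded direct
measurement (the waveform-lidar elevation feature).

*Quantiles* follow the quantile-regression-forest construction: each
query row weights every training observation by its co-leaf frequency
(equal weight per tree across the leaf's training occupants — in-bag and
out-of-bag — normalized over trees), and the returned quantile is the
smallest training response whose cumulative weight reaches q. Quantiles
are non-decreasing in q by construction. Prediction maps clip to the
display range [0, 9].

*Residual correlograms* use Moran's I with binary distance-band weights
and a two-sided permutation test around E[I] = −1/(n−1); empty bands are
reported missing. No spatial term enters the models themselves —
correlograms are diagnostics only.

## What the synthetic tests do and do not show

Passing recovery tests demonstrate that each metric implementation
extracts what its simulator encodes and that the modeling machinery
attributes signal to the right sensor family — under clean geometry,
known noise and a single shared projection. They do not validate
radiometric calibration, geolocation, atmospheric effects, phenology
timing, or detection processes of real campaigns, and the per-species
accuracies obtained on synthetic scenes carry no information about real
census accuracies.

## Problem sizes and numerical choices

Test landscapes are sized for a single CPU: the recovery landscape is
2,000 × 1,000 m with 100 m plot spacing (200 plots, ~80k stems, ~3.5M
lidar returns); the ten-seed importance-recovery runs use 1,200 × 600 m
(72 plots); quantile-interval calibration uses a purely statistical
linear-Gaussian fixture (y = x + N(0, 1), n = 2,000) where the
conditional distribution is known in closed form. All randomness flows
through explicitly passed seeds, with pipeline stage seeds derived from
one base seed by fixed offsets; identical (config, seed) pairs reproduce
every product bit-for-bit. Degenerate inputs have defined behavior
throughout: empty plots yield zero density and missing distribution
stats, treeless scenes yield floor-level radar and soil NDVI, zero-signal
waveforms raise a no-signal error that the feature table converts to a
logged exclusion.
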