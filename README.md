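# canopyfuse

Multi-sensor remote-sensing fusion for forest songbird habitat mapping,
exercised entirely on synthetic data.

## The problem

Mapping where forest birds persist across a landscape requires habitat
structure that no single remote-sensing instrument captures alone:
vertical canopy structure (lidar), stand composition and phenology
(multispectral), and woody-structure backscatter (radar). This package
re-creates that analysis chain end to end for a bowl-shaped forested
watershed with census plots on north–south transects, where the response
is **prevalence** — the number of years (0–9) a species was detected at a
plot over a 9-year census.

Because no field or flight data are deposited for such campaigns, a
first-class synthetic-data layer generates the ground truth (terrain,
marked stem maps with height/crown allometry, a conifer↔deciduous
elevation gradient, and prevalence drawn from known logistic
species–habitat responses), and simulators produce the four observation
types from it:

* **discrete-return lidar** (≥1 pulse/m², ≤4 returns) → 0.5 m DSM/DEM/CHM,
  adaptive local-maxima tree detection, stem density, and crown-area-weighted
  height ∑(Caᵢ·Hᵢ)/∑Caᵢ (the crown-area analogue of Lorey's height);
* **large-footprint waveform lidar** (25 m footprints) → ground-corrected
  relative-height energy quantiles RH25/RH50/RH75/RH100, total canopy
  cover, and the canopy-cover profile in 5 m bins;
* **L-band polarimetric radar** (5 m HH/VV/HV with gamma speckle) → linear
  power, 3×3 gamma-MAP filtering, band ratios and normalized difference
  indices such as (HH−VV)/(HH+VV);
* **two-season multispectral** (30 m red/NIR) → NDVI and leaf-on minus
  leaf-off NDVI change (deciduousness).

All metrics are aggregated over 88.8 m plot pixels (0.79 ha, matching the
50 m count circles) into a fixed **104-column predictor matrix**
(radar 36, Landsat-style 4, waveform lidar 50, discrete-return lidar 14).

## The model

Prevalence is modeled as a continuous response with bagged regression
forests: per species, five models (one per sensor family plus the fusion
of all 104 predictors), each with 800 trees, ⌊p/3⌋ candidate predictors
per split, and explicit out-of-bag (OOB) bookkeeping. Accuracy is the OOB
variance explained,

    pseudo-r² = 1 − MSE(y, ŷ_OOB) / Var(y),

importance is the increase in per-tree OOB MSE when a predictor is
permuted, and prediction uncertainty comes from quantile regression
forests (the weighted empirical distribution of co-leaf training
responses), mapped wall-to-wall as 10th/50th/90th-percentile prevalence
rasters. Moran's I correlograms of OOB residuals diagnose leftover
spatial autocorrelation.

## Worked example

`examples/05_fusion_models.py` simulates a 900 × 500 m campaign, fits the
five models for the black-throated-blue-warbler archetype (a low-elevation
deciduous-forest species) and maps its prevalence:

```
OOB pseudo-r2 (variance explained) per model, BTBW:
      radar  landsat    drl   lvis  fusion
BTBW  0.419     0.43  0.763  0.671   0.753

top 5 fusion predictors by permutation importance:
lvis_elev_mean                    2.0693
drl_height_mean                   1.4177
drl_h_diam_mean                   1.2313
drl_crown_diam_mean               1.1796
drl_crown_area_weighted_height    1.1157

prevalence map: (6, 10) pixels, range 0.6-7.7 detection-years
mean 80% prediction-interval width: 4.17 detection-years
```

Radar alone explains least, lidar most, and fusion matches the best
single sensor — the qualitative ordering expected when each sensor sees a
different slice of the habitat signal. The importance ranking identifies
elevation and canopy-structure metrics as the drivers, which is exactly
how this species' prevalence was generated. The other examples
(`examples/01–04`) walk through scene simulation, the lidar metric
chains, radar/NDVI derivation and feature-table assembly, each printing
the quantities it computes.

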