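# rseitools

Growing-season ecological quality analysis from remote-sensing index time
series: harmonic gap-filling (HANTS), the PCA-based Remote Sensing
Ecological Index (RSEI), Sen + Mann–Kendall trend and breakpoint
analysis, Moran's I / LISA spatial autocorrelation, geodetector driver
attribution, and land-cover transition accounting — packaged as a tested
pipeline that runs end-to-end on a synthetic Landsat-like scene generator,
so every stage is verifiable without downloading imagery.

## Who this is for

Remote-sensing ecologists who assess regional ecological quality from
Landsat-class surface reflectance. Cloud-prone growing seasons leave
index time series (NDVI, tasseled-cap wetness, dryness, land surface
temperature) gappy and noisy; this package reconstructs them, composites
them, condenses them into a single quality score per year, and then asks
where, when, and why that score changed.

## The model

**HANTS.** Each pixel's index series is fit by least squares to a mean
plus `nf` harmonics,

```
ỹ(t) = a0 + Σᵢ [ aᵢ cos(2π fᵢ t) + bᵢ sin(2π fᵢ t) ],   fᵢ = i / base_period,
```

which smooths noise and evaluates at any time, filling cloud gaps. A
pixel needs ≥ 2·nf + 1 valid samples. Reconstruction quality is judged by
Pearson R, STD and RMSE against the original series (Taylor-diagram
statistics), swept over nf = 1…10.

**RSEI.** Per year: water is masked with MNDWI, the four component
indices (greenness NDVI, wetness TCW, dryness NDBSI = (SI + IBI)/2, heat
LST) are min-max normalized, and PC1 of their 4×4 covariance is taken.
If the NDVI and TCW loadings are negative the score is flipped (1 − PC1)
so that higher = ecologically better, then rescaled to [0, 1] and
classified poor / fair / moderate / good / excellent in 0.2-wide bins.

**Trends.** Sen's slope (median of pairwise slopes, the printed mean
variant selectable) plus the Mann–Kendall test with tie-corrected
variance and continuity correction classify per-pixel trends at the
|Z| = 1.96 / 2.58 cutoffs. Turning years of the annual mean series are
found by exhaustive piecewise-OLS search minimizing the summed
per-segment cost J = Σ (1/2m) Σ (h(x) − y)², each segment ≥ 3 points.

**Space and drivers.** RSEI is fishnet-sampled, queen-contiguity weights
built, and global/local Moran's I computed with conditional-permutation
LISA classes (HH/LL/LH/HL/not significant). The geodetector q-statistic
q = 1 − SSW/SST measures how much each stratified driver (temperature,
precipitation, slope, aspect, altitude, class ratios) explains the
quality surface, and pairwise interactions are categorized against
q(X1), q(X2) per the standard five-way rule table.

## Worked example

```python
import rseitools as rt

cfg = rt.PipelineConfig.from_dict({
    "scene": {"grid_shape": [32, 32], "n_years": 5, "obs_per_season": 10,
              "trend_slopes": {"forest": {"NDVI": 0.004},
                               "cropland": {"NDVI": -0.006, "NDBSI": 0.006},
                               "impervious": {"NDBSI": 0.004, "LST": 0.2}}},
    "k_breaks": 0, "moran_permutations": 99, "detector_permutations": 49,
    "seed": 11})
rt.run(cfg, "rsei_demo")
```

`rsei_demo/rsei_summary.csv` then holds the annual PC1 loadings,
contribution rate and mean RSEI:

```
year  NDVI   TCW  NDBSI  LST  contribution_rate  rsei_mean
   0 -0.50 -0.56   0.58 0.31              97.35       0.75
   1 -0.48 -0.55   0.56 0.39              97.46       0.75
   2 -0.51 -0.48   0.62 0.36              97.63       0.71
   3 -0.49 -0.52   0.57 0.42              97.07       0.74
   4 -0.51 -0.54   0.58 0.35              97.72       0.74
Mean -0.50 -0.53   0.58 0.37              97.45       0.74
```

The negative NDVI/TCW loadings trigger the 1 − PC1 orientation (the
familiar pattern for this index family); the contribution rate says PC1
carries ~97% of the joint index variance on this synthetic scene, and
mean RSEI ≈ 0.74 reflects the scene's forest-dominated composition.
`moran_global.json` reports I = 0.559 (expected −0.017 under no
autocorrelation, pseudo-p = 0.01): the quality surface is spatially
clustered, as built. `detector.csv` ranks forest ratio (q = 0.63) and
impervious ratio (q = 0.47) as the strongest drivers — the planted
land-cover control of quality.

The same stages are scriptable from the shell:

```
rsei run-all -c config.yaml -o out/
rsei validate -c config.yaml
```

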