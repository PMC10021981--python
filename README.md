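# sors — spatial obesity risk scoring from points of interest

`sors` builds a **Spatial Obesity Risk Score (SORS)**: a continuous risk
surface over a study area derived from the local density of *obesogenic*
environmental features (fast-food outlets, pastry and sweets shops, bars, …)
relative to *protective* ones (supermarkets, gyms, parks, bus stops, …).
It is aimed at spatial epidemiologists and public-health researchers who
want to map, compare and monitor the obesogenic environment from
OpenStreetMap-style point-of-interest (POI) exports, and to understand how
sensitive such maps are to the modelling choices behind them.

## The model

POIs are split into two layers and each layer is smoothed with a weighted
isotropic bivariate Gaussian kernel density estimate on a shared grid:

```
f_L(s) = Σ_i w_i φ_h(s − s_i) / Σ_i w_i          L ∈ {obesogenic, protective}
SORS(s) = f_obesogenic(s) − f_protective(s)
```

Positive values mean obesogenic dominance (higher environmental obesity
risk).  The pieces around that core:

- **Equidistant planar frame.** Geographic coordinates are scaled by
  `x = (lon − lon₀)·cos(ref_lat)`, `y = lat − lat₀`, with a synthetic origin
  southwest of all data, so one x-unit and one y-unit span the same ground
  distance.  Dense bus-stop groups are reduced to DBSCAN cluster centroids.
- **Edge correction by window expansion.** The observation window scales
  each side of the study area's bounding box ("exact box") concentrically;
  the base case uses factor 1.4.  The grid puts 25 cell-center nodes per
  dimension on the exact box plus 10 per additional 0.4 of expansion, which
  keeps node spacing and interior node locations identical across factors.
- **Bandwidth.** Terrell's oversmoothing (maximal-smoothing) bandwidth,
  `h = 0.9662·σ·n^(−1/6)`, computed on the pooled union of both layers so
  both surfaces are smoothed alike.
- **Spatial heterogeneity check.** Ripley's K function with closed-form
  isotropic edge correction on the rectangular window, with Loh bootstrap
  confidence bands (resampling per-point K contributions), classifies each
  layer as clustered / regular / indistinguishable versus the Poisson
  reference `πr²`.
- **Interpolation.** Scores at arbitrary interior points via bilinear
  weights (base case), four-node inverse-distance weighting, nearest node,
  or ordinary kriging with a WLS-fitted zero-nugget variogram.
- **Sensitivity + uncertainty.** Nineteen labelled scenarios vary one
  parameter at a time (bandwidth ×{⅓,⅔,1,4⁄3,5⁄3}; expansion factor
  {1.4,…,3.0}; 35/70/105 grid nodes; four interpolators; equal vs doubled
  supermarket/gym weights).  A fixed spatial bootstrap (with-replacement
  resamples per layer, shared across scenarios) propagates POI uncertainty;
  each scenario's N×B score matrix at N random evaluation points is
  condensed into a one-way ANOVA F statistic — between-location variance
  over within-location bootstrap variance — so scenarios can be ranked by
  how sharply they discriminate low- from high-risk places.
- **Cross-method comparison.** A log-quadratic inhomogeneous Poisson
  intensity (Berman–Turner quadrature, weighted Poisson regression) is
  fitted per layer; the mass-normalised intensity difference gives an
  independent score surface to compare patterns against.

A synthetic data generator (Thomas cluster processes with OSM-style tags and
a star-shaped boundary) makes the whole pipeline runnable and testable
without any downloads.

## Worked example

```python
from sors import SORSModel, SensitivityAnalysis
from sors.synthgen import SyntheticConfig, synthesize_dataset

poi, boundary, truth = synthesize_dataset(SyntheticConfig(seed=0), "data/")
model = SORSModel.from_geojson(poi, boundary)
results = model.fit()
print(results.summary())
```

```
Spatial Obesity Risk Score
==========================
POIs: 268 obesogenic, 166 protective
Observation window: expansion factor 1.4, grid 35 x 35
Bandwidth: h = 0.00800625 planar units (Terrell x 1, pooled n = 434, sigma = 0.0227994)
Weighting: equal
Score range: [-219.897, 358.035]  (positive = obesogenic dominance)
Density window integrals: obesogenic 0.9725, protective 0.9406
```

The bandwidth `h ≈ 0.008` planar units is roughly 900 m at this latitude —
the maximal defensible smoothing for 434 pooled points.  The score range is
in density units (per planar-area unit); its sign field is what the risk
map shows.  Checking heterogeneity and running the sensitivity analysis:

```python
kest, verdict = results.ripley("obesogenic", B=1000, seed=0)   # -> "clustered"
sens = SensitivityAnalysis(model, n_eps=50, B=100, seed=0).run()
print(sens.summary())
```

```
      area scenario       parameter       F
study area      BW1       bandwidth  579.22
study area      BW2       bandwidth  835.52
study area      BW3       bandwidth 1028.29
...
Relative influence per parameter family ((max F - min F) / base F):
  bandwidth        0.458
  weighting        0.016
  interpolation    0.012
  grid_points      0.002
  edge_correction  0.000
```

Here F ≈ 1028 at the base case means the between-location spread of scores
is three orders of magnitude larger than their bootstrap noise — the score
discriminates locations robustly — and the bandwidth is by far the most
influential modelling choice, consistent with the sensitivity ordering the
method was designed to expose.  (With a fixed POI file, window expansion
only adds exterior grid nodes, so its influence is exactly zero; see
`docs/methods.md`.)

A CLI mirrors the library: `sors simulate`, `sors ingest`, `sors kfunction`,
`sors score`, `sors evaluate`, `sors ppcompare` — run any with `--help`.

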