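# Methods

This note documents the statistical model behind `sors`, the choices made
where the design was genuinely open, and what the synthetic-data tests do
and do not establish.

## Coordinate frame

The pipeline works in an *equidistant planar frame*: an equirectangular
scaling `x = (lon − lon₀)·cos(ref_lat·π/180)`, `y = lat − lat₀`.  The
reference latitude is the mean latitude of the joint bounding box of POIs
and boundary, which minimises scale distortion across the window; the
synthetic origin sits 0.05° southwest of that box so all planar coordinates
are positive.  Over a ~30 km extent at mid-latitudes the scaling agrees
with great-circle distances to well under 1 % (tested against a haversine
oracle), which is ample for kernel smoothing; no projected CRS machinery is
used or needed.  Planar units are degrees of latitude (≈ 111 km).

Bus stops are a special case: raw exports list every platform of an
interchange separately, which would overweight public transport.  Dense
groups of the `Bus_stop` subcategory are collapsed to DBSCAN cluster
centroids (defaults `eps = 0.004` planar units ≈ 300 m near 48° N,
`min_samples = 3`, both configurable).  Noise points are *retained* as
singletons — sparse rural stops are real data — and the centroid carries
weight 1: the reduction removes redundancy, it does not re-weight the
cluster.  Both conventions are open choices; the alternatives (dropping
noise, weight = cluster size) are one-line changes.

## Window, grid and edge correction

The *exact box* is the bounding rectangle of the study boundary.  The
observation window scales both side lengths by an expansion factor
(base 1.4) about the same center.  The enlargement is the edge correction
for the density surfaces: kernels centred outside the boundary contribute
mass at the border, so border densities are not truncated.

The grid places nodes at **cell centers** of an n×n partition: 25 per
dimension on the exact box, plus 10 per additional 0.4 of expansion factor.
With `nx = 25 + 10k` on a window of width `(1 + 0.4k)·W` the spacing is
`W/25` for every `k`, and the lattice at step `k+1` equals the lattice at
step `k` extended by exactly 5 whole cells per side — interior node
locations are preserved *exactly* across the edge-correction scenarios.
An endpoint (fencepost) lattice has neither property; this is why cell
centers were chosen.  The grid-point scenarios (70², 105²) instead override
the node count at the base factor 1.4.

## Bandwidth

The base bandwidth is Terrell's maximal-smoothing (oversmoothing) choice
for the bivariate Gaussian kernel,

    h = C₂ · σ · n^(−1/6),      C₂ = (2500/3072)^(1/6) ≈ 0.96624,

where `σ = sqrt((s_x² + s_y²)/2)` is computed on the **pooled union** of
both layers and `n` is the pooled count.  Pooling gives both surfaces the
same smoothing, so their difference compares like with like; the constant's
derivation from the maximal-smoothing principle is in the source.  Scenario
bandwidths multiply `h` by {⅓, ⅔, 1, 4⁄3, 5⁄3}.  `h` is scale-equivariant
and shrinks as `n^(−1/6)`; both laws are asserted in tests.

## Density surfaces and the score

Each layer's surface is a weighted mixture of isotropic Gaussians that
integrates to one over the plane (probability density, not intensity).
Consequence: the score compares the *shapes* of the two layers, not their
absolute counts — a region can score negative even where obesogenic POIs
outnumber protective ones overall.  This matches what standard KDE tooling
produces, keeps the difference stable when layer sizes differ, and is the
main interpretive caveat of the score.  Density mass may legitimately fall
outside the window (never above 1 + 1e-6); at expansion factor 3 with
interior data the window captures ≥ 0.999 of it.

The score is `SORS = f_obesogenic − f_protective`, so positive values mean
obesogenic dominance.  The sign convention is exposed; swapping the inputs
negates the surface exactly.

## Ripley's K and the Loh bootstrap

Spatial heterogeneity is tested per layer (unweighted) with

    K̂(r) = |W| / (n(n−1)) · Σ_{i≠j} w_ij · 1{d_ij ≤ r},

where `w_ij ≥ 1` is the reciprocal of the fraction of the circle of radius
`d_ij` about point *i* lying inside the rectangular window — computed in
closed form (side arcs minus corner overlaps) and cross-checked against
dense numeric arc sampling to 1e-6.  K is computed on the expansion window,
not the irregular municipal polygon: the rectangle admits an exact
correction, and the choice is documented rather than hidden.  Confidence
bands follow Loh: K̂ is the mean of per-point contributions
`K_i(r) = (|W|/(n−1)) Σ_j w_ij 1{d_ij ≤ r}`; resampling the `K_i` with
replacement B times (default 1000) and taking empirical α/2 and 1−α/2
quantiles of the resampled means gives the band (α = 0.05).  A layer is
clustered at distance r when the lower band exceeds `πr²`, and clustered
overall when that happens for at least one r.

## Interpolation

Four methods read the score off the grid: bilinear (base case; exact for
affine surfaces), inverse-distance weighting over the four enclosing nodes
(Shepard power 2, the standard default — the source does not prescribe
one), nearest node (ties to the lower row/column index), and ordinary
kriging.  Kriging uses a variogram fitted to the node values by weighted
least squares (weights √pair-count, exponential and spherical candidates,
nugget fixed at 0 because node values are noise-free computed quantities —
this keeps kriging an exact interpolator), with a 64-node search
neighbourhood.  Empirical semivariances are fitted only up to 0.35 of the
window diagonal: single-realization variograms are unreliable at lags
comparable to the window and inflate the fitted range otherwise.  The
variogram is fitted once on the base (non-bootstrap) surface per scenario
and reused across replicates.

All four methods are linear in the node values, so each evaluation point
reduces to a fixed weight vector over nodes; the sensitivity analysis
computes these weights once per scenario and applies them to every
bootstrap surface — algebraically identical to per-replicate interpolation
and roughly two orders of magnitude faster.

## Sensitivity analysis, bootstrap and ANOVA

Nineteen scenarios in five one-at-a-time families (BW1–5, EC1–5, GP1–3,
INT1–4, WT1–2) share the base case (Terrell ×1, factor 1.4, 35×35,
bilinear, equal weights).  Uncertainty in POI composition enters through a
spatial bootstrap: B with-replacement resamples per layer, drawn **once**
and reused for all scenarios, so F differences across scenarios reflect
settings only (paired comparability).  Per replicate, the pooled bandwidth
is **recomputed on the resample** (h is data-dependent) and then scaled by
the scenario multiplier; a flag can freeze the full-data h instead.

Each scenario yields an N×B score matrix at N fixed evaluation points
(uniform rejection samples inside the boundary; N = 50 by default), and

    F = [Σ_i B(ȳ_i − ȳ)² / (N−1)] / [Σ_i Σ_b (y_ib − ȳ_i)² / (N(B−1))]

— the one-way ANOVA statistic with evaluation points as groups.  Higher F
means locations are better separated relative to bootstrap noise.  F is
invariant to affine transformations of the scores; zero within-group
variance returns +inf with a warning.  The *relative influence* of a
parameter family is reported as `(max F − min F) / F_base` — an explicit,
simple normalisation chosen here (the field has no canonical one); raw F
values are always reported alongside.

**Known structural property:** with the POI file fixed, enlarging the
window only adds exterior grid nodes — the mass-1 KDE value at an interior
node does not depend on the window, and evaluation points are interior —
so the edge-correction scenarios produce *identical* score matrices and
their influence is exactly zero.  In a live-download workflow the enlarged
window is also the download area, new POIs enter, and edge correction
matters; reproducing that requires re-reading a larger POI file per
scenario, which is outside this package's fixed-input contract.

## Point-process comparison

As an independent view of the same data, each layer is fitted as an
inhomogeneous Poisson process with log-quadratic intensity via the
Berman–Turner device: quadrature points (40×40 cell centers plus the data
points) carry counting weights `cell area / points in cell`, and a weighted
Poisson regression of `1{data}/w` on the polynomial basis maximises the
discretised likelihood `Σ log λ(s_i) − ∫ λ`.  A degree-0 fit recovers
`n/|W|` exactly, and the fitted total mass matches the observed count (the
MLE score equation) to ~1 %.  Only the first-order trend is fitted — this
equals the composite-likelihood trend fit of a cluster process; estimating
cluster variance parameters or selecting among cluster families is out of
scope.  The comparison surface is the difference of the two intensities
after each is normalised by its fitted mass, putting it on the same
density scale as the score; on the default synthetic fixture its sign
agrees with the KDE score at ≈ 72 % of grid nodes.

## Synthetic data

The generator emulates a small-town OSM export: per layer, a Thomas
cluster process (Poisson parents, Gaussian-dispersed Poisson offspring;
parents drawn on a 4σ-padded window to avoid border thinning) on a
0.1°×0.1° window, with OSM tags drawn from fixed per-layer mixtures and a
star-shaped boundary polygon.  Defaults (`κ = 2000 /deg²` obesogenic,
`1600 /deg²` protective; `μ = 12/14`; `σ = 0.004/0.005° ≈ 400–500 m`)
give a few hundred POIs per layer — the scale of a rural town — with the
clustered character real POI data shows, and clusters of roughly
street-block extent.  What the generator does **not** emulate: street-network
alignment, population-weighted siting, tag noise/duplicates, and any true
association between the two layers (they are independent processes).
Passing tests therefore establish the machinery's correctness and
calibration, not substantive conclusions about any real town.

Problem sizes used in the shipped checks — 200 CSR replicates of n = 200
for K calibration, 100 Thomas seeds for cluster detection, B = 100
bootstrap replicates with N = 50 evaluation points for the 19-scenario
analysis, 20 simulated fields for variogram recovery — were chosen so the
whole suite runs in well under a minute while leaving Monte-Carlo error
comfortably inside the asserted tolerances.

## Numerical details and degenerate inputs

- KDE evaluation uses the separable kernel factorisation
  `(G_x · w) G_yᵀ`, exact for the isotropic Gaussian.
- Isotropic K weights fail loudly if a circle has no arc inside the window
  (p ≤ 1e-12); this cannot occur for the r-grid default (≤ ¼ of the
  shorter side).
- Kriging systems are solved directly; a singular system falls back to
  bilinear with a warning.  Kriging predictions may leave the local data
  range (no convexity), unlike the other three methods.
- Ties in nearest-node interpolation break to the lower (row, column)
  index; IDW at zero distance returns the node value.
- Zero pooled dispersion (all points coincident) and empty layers raise
  errors rather than producing degenerate surfaces.
- Bootstrap resamples of a single-point layer are that point repeated; the
  ANOVA sentinel (+inf) covers the all-identical-scores corner.

## Limitations

- The score is a density difference: it ranks places within a study area
  but carries no absolute risk scale, and equal-mass normalisation hides
  layer-size imbalance.
- The category mapping ships with a literature-motivated default covering
  unhealthy food, healthy food, physical activity, green space and public
  transport; it is configuration, not a validated instrument, and users
  should supply their own for serious use.
- Edge-correction sensitivity cannot be observed with a fixed POI file
  (see above).
- The rectangular K window slightly dilutes clustering evidence when the
  boundary is much smaller than its bounding box.
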