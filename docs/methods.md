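# Methods

This note documents the models, the synthetic study system, the numerical
choices and the known limitations of `socmap`. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Spatial model

SOC concentration (and SOC stock, which is concentration times a per-site
conversion) is treated as a lognormal random field over a projected,
planar-metric domain: on the natural-log scale it is a stationary Gaussian
random field with an exponential semivariogram

γ(h) = c₀ + c·(1 − e^(−h/a)),  h > 0,

plus a per-stratum additive mean (the three land-use classes differ in
their mean log-SOC but share one residual variogram). The nugget c₀
aggregates micro-scale variation and measurement error; the sill c₀ + c is
the log-scale variance; the effective range (95 % of the sill) is ≈ 3a.
Spatial dependence is classified by the nugget-to-sill ratio with the
conventional 25 % / 75 % cut points.

All distances everywhere in the package are Euclidean in metres; rasters
use the lower-left-origin, row-0-south, cell-centre convention of the ESRI
ASCII grid format.

## The synthetic mountain park

The generator emulates a ~482 km² volcanic park (22 km × 22 km square,
2,200–4,461 m a.s.l.) surveyed at 440 sites. Design choices, with the
tunable parameter in parentheses:

* **Relief** (`cone_exponent` 1.3, `dem_noise_amp` 40 m, `dem_noise_scale`
  1 km): a radial cone profile `(1 − (r/R)^1.3)` plus smooth seeded noise.
  The exponent 1.3 was chosen once so the altitude bands reproduce
  realistic class areas — about 53 % seasonal agriculture, 39 % forest and
  7 % grassland/high moor.
* **Land use by altitude band** (upper-closed bands): agriculture up to
  3,000 m, forest 2,500–4,000 m, grassland above 4,000 m. In the
  2,500–3,000 m overlap the class is Bernoulli with forest probability
  0.3, drawn by thresholding a smoothed noise field at the matching
  quantile (`mixed_patch_scale_m` 1.5 km). The marginal probability is
  exact; the spatial coherence makes the mosaic contiguous patches rather
  than cell-level salt-and-pepper, which would otherwise inject a huge
  artificial nugget at stratum boundaries.
* **SOC field** (nugget 0.529, sill 2.226 log-scale, range 3 km): the GRF
  is simulated by circulant embedding on a doubled torus (FFT; negative
  embedding eigenvalues, which are negligible at range ≪ extent, are
  clipped), nugget noise is added per cell, and each stratum's log-mean is
  set to ln(mean) − sill/2 so the back-transformed stratum means are
  5.19 (agriculture), 40.31 (forest) and 12.82 (grassland) g kg⁻¹ in
  expectation. The range default (3 km ≈ park radius / 4) keeps the
  structure well inside the extent so it is recoverable from a survey.
  **Consequence:** the field-level variogram governs within-stratum
  dispersion. A log-variance of 2.226 implies a coefficient of variation
  of ≈ 287 %, far above the tabulated survey CVs (~40 %); the per-stratum
  `sd_soc` values are therefore carried as descriptive survey statistics
  only, and the generator's dispersion tests check the log-scale SD
  against √sill, the value the generative model actually implies. Matching
  both the field variogram and the tabulated stratum SDs is mathematically
  impossible; the variogram wins because the geostatistical pipeline is
  the object under test.
* **Survey design**: one jittered point per ~1 km block (the 100-ha grid
  template), thinned to 440, so stratum counts are proportional to class
  areas. Bulk density ~ U(0.9, 1.4) g cm⁻³, coarse fragments ~ U(0, 20) %,
  O-horizon thickness exponential around the stratum mean (5.31 cm forest,
  1 cm grassland, none under agriculture), O-horizon SOC ~ U(284.76,
  484.20) g kg⁻¹. The O-horizon bulk density (0.15 g cm⁻³) is a synthetic
  knob: organic layers are light, and some value is needed to exercise the
  stock equation on the O horizon at all.
* **NDVI** (intercept 0.32, slope 0.15, noise SD 0.05): clip(intercept +
  slope·standardize(log SOC) + noise, −1, 1). Standardising on the log
  scale keeps the link monotone in SOC while spreading the heavy-tailed
  field over a realistic greenness band (forest NDVI ≈ 0.23–0.46); the
  resulting cell-level Pearson correlation with raw SOC is ≈ 0.5.

Determinism: one master seed feeds a `SeedSequence`; each stage (DEM,
land use, field, NDVI, survey) draws from its own spawned stream, so the
same seed reproduces every artifact bit-for-bit on any platform with the
same numpy PCG64 generator.

What the generator does **not** emulate: canyons and aspect-driven
microclimate, within-stratum trends (e.g. the observed mid-altitude SOC
maximum), measurement-protocol error structure, and the field campaign's
deliberate oversampling of forest. Passing tests therefore demonstrate
that the pipeline's statistics behave correctly on a well-specified
lognormal field with categorical trend — not that any particular real
mountain obeys that model.

## Variogram estimation and fitting

Empirical semivariograms use half-open distance bins; each occupied bin
reports the **mean pair distance** (not the midpoint) as its lag, which
removes the short-lag aggregation bias that otherwise inflates the fitted
nugget. Default binning for mapping: 15 lags to half the maximum pairwise
distance. Fitting minimises the Cressie objective Σ N(h)·(γ̂/γ_model − 1)²
with non-negativity bounds, five deterministic initialisations, and two
identifiability guards: the range is capped at twice the largest observed
lag (beyond that the sill is unidentified and the fit can drift along a
flat valley), and structure whose fitted range is below a third of the
first observed lag is folded into the nugget (the two are
indistinguishable there).

**Parameter recovery protocol** (`recover_variogram`): the stationary
variogram belongs to the stratum-demeaned residual, so per-stratum sample
means are removed from log SOC first; the fit is then restricted to lags
within twice the range parameter (two thirds of the effective range) with
bins about one survey spacing wide. Long lags carry no curvature
information about a bounded model and only add noise to the weighted
least squares; with this window the nugget estimator is unbiased on the
default survey, with a sampling SD of ≈ 0.13 — recovery of nugget and sill
to ±30 % succeeds in roughly three quarters of seeds individually, which
is what the 8-of-10-seeds acceptance check reflects. This precision is an
information limit of the 1-km survey spacing (few close pairs), not a
fitting deficiency.

## Interpolation engines

All six engines share a nearest-neighbour search (default 15 neighbours,
minimum 4, unlimited radius — the common GIS default) and are
translation-equivariant by construction. Duplicate coordinates are
averaged (with a warning) before any kriging; RBF rejects them by naming
the offending pair, since its system is otherwise singular.

* **IDW**: β = 2 default; a target within 10⁻⁹ m of a site snaps to the
  site value.
* **LPI**: weighted local polynomial (order 1 default) with kernel
  (1 − h/b)²; the default bandwidth is twice the farthest-neighbour
  distance, giving the smooth trend surface characteristic of the method.
  Rank-deficient local systems fall back to an order-0 weighted mean with
  a logged warning.
* **RBF**: exact interpolation with thin-plate spline (linear trend),
  spline with tension and completely regularized spline (K₀- and
  E₁-based kernels, Euler-constant normalised so φ(0) = 0), multiquadric
  and inverse multiquadric (constant trend). Local coordinates are
  rescaled to unit mean distance for conditioning. The shape parameter is
  optimised per neighbourhood by leave-one-out error using Rippa's
  shortcut (LOO residual = weight / diagonal of the inverse matrix) over a
  log-spaced candidate grid; candidates whose system residual betrays
  ill-conditioning are skipped. Without this optimisation the flatter
  kernels oscillate wildly on noisy data.
* **OK**: per-target semivariance system with a Lagrange multiplier
  enforcing unit weight sum; kriging variance floored at zero with a debug
  log (theory guarantees non-negativity; floating point does not).
* **CK**: *collocated* ordinary cokriging in covariance form — secondary
  variables (up to four; NDVI, altitude, slope in the pipeline) are
  sampled at the training sites and at each prediction location. The
  collocated value is what lets a cross-correlated covariate cut the
  prediction variance below OK's nugget floor. The linear model of
  coregionalization uses two common structures (nugget + the primary's
  structure); the primary's direct coefficients are held fixed at the
  supplied variogram, secondary and cross coefficients are fitted by
  weighted least squares and the coefficient matrices are projected onto
  the PSD cone with the primary entries pinned (alternating projection).
  Secondaries with (near) zero fitted variance are dropped with a warning,
  collapsing CK to OK exactly; the system is solved by least squares so a
  perfectly redundant secondary degrades gracefully instead of crashing.
* **EBK** (simplified): sites are partitioned by recursive median splits
  into subsets of ≤ 100, each grown by 50 % nearest outside sites; each
  subset gets an exponential fit plus parametric-bootstrap refits
  (bin values perturbed by their approximate sampling SD γ√(2/N), then
  refitted) — the "spectrum of semivariograms". A target mixes OK
  predictions across the nearest (≤ 2) subsets with inverse-squared
  centroid-distance weights, uniformly across simulations; the reported
  variance is the total variance of that mixture, so the EBK standard
  error dominates the single-model OK standard error. With one subset and
  one simulation EBK collapses to OK exactly. This is a published-contract
  re-creation; the proprietary restricted-ML intrinsic-random-function
  algorithm of commercial GIS suites is not published at implementable
  detail.

## Cross-validation design

One stratified hold-out split: 45 validation sites (quota 7 grassland /
17 forest / 21 agriculture) with pairwise spacing ≥ 1 km, found by seeded
rejection sampling (up to 1,000 draws; if the constraint cannot be met the
best-separated draw is returned and flagged). Error indices: ME, RMSE,
MRE = RMSE / (observed validation range), and R² as the squared Pearson
correlation (bounded [0, 1]; the referent of Δ and the exact R² definition
are conventions this package fixes explicitly). When the variogram is
modelled on log values the comparison is run, and scored, on the log
scale.

Method rankings between well-matched interpolators (OK vs IDW differ by
~1 % RMSE here) are inside single-split noise at 45 validation points, so
the acceptance harness asserts rankings on the mean indices across five
replicate seeded surveys while still requiring every individual replicate
to produce the full six-method table with finite indices. On those
replicate means, collocated CK ranks first by a wide margin (it alone sees
the NDVI surface at prediction locations), OK is at least as accurate as
IDW, and both kriging variants outrank the LPI smoother.

## Stock accounting

A-horizon thickness is fixed at 15 cm; the O horizon uses its measured
thickness, the configurable organic bulk density, and no coarse-fragment
correction (organic layers are taken stone-free). Landscape summaries use
the n−1 SD and linear-interpolation (type-7) quartiles. Totals are
mean density × area × 10⁻⁶ (t C ha⁻¹ × ha → Tg C). Scenario accounting
reassigns a converted landscape's area the all-horizon per-hectare density
of its target landscape; the historical-forest scenario is exposed the
same way (all → forest with a user-supplied preserved-forest density)
rather than as a hard-coded constant, because no derivation exists for a
fixed value.

## Numerical details and edge cases

* Snap tolerance 10⁻⁹ m for coincident points throughout.
* Empty variogram bins carry NaN and zero pair count; fits require ≥ 4
  occupied bins; an all-zero variogram (constant field) is an error.
* Rasterization assigns a cell centre on a shared polygon edge to the
  first-listed polygon (deterministic tie-break); uncovered cells are
  nodata.
* Slope uses Horn's 3×3 stencil; border cells are nodata, with an
  edge-fill helper for when slope serves as a covariate.
* ESRI ASCII files are written north-row-first and flipped on read;
  GeoTIFFs carry ModelPixelScale / ModelTiepoint / GDAL nodata tags.
* NDVI cells with NIR + RED = 0 are nodata; annual compositing is the
  per-cell mean of valid months (max-value compositing available).

## Limitations

* No anisotropy, no universal/regression kriging, no REML variography.
* Back-transformation of log-scale kriging to the original scale is left
  to the user; the pipeline reports log-scale indices when it models on
  the log scale.
* The EBK re-creation shares the published contract (subsets, simulated
  variogram spectrum, mixture variance) but not the proprietary
  estimator, so its absolute numbers are not comparable to commercial
  implementations.
* Stock uncertainty is not propagated; totals are plug-in products of
  means and areas.
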