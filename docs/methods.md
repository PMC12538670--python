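# Methods

This note documents the models, conventions, and numerical choices behind
`fluxgpr`, and what the synthetic test bed does and does not demonstrate.

## Regression model

Each flux variable (GPP, RECO, NEE; μmol CO₂ m⁻² s⁻¹, daily means) gets its
own exact GP with an ARD squared-exponential kernel on standardized inputs
and a zero-mean prior on the standardized target.  Standardization constants
are estimated from the training rows and stored with the model, so raw-unit
prediction is exact; during cross-validation they are recomputed on each
training fold to avoid leakage.

**Hyperparameter search.**  The marginal likelihood is maximized with
L-BFGS-B over log-hyperparameters.  The first start is deterministic
(σ_s² = 1, all lengthscales 1, σ_n² = 0.1 in standardized units); further
restarts draw log-uniformly from [1e-2, 1e2] for signal variance and
lengthscales and [1e-4, 1] for noise variance.  Box bounds are [1e-2, 1e2]
(lengthscales, signal) and [1e-8, 1e2] (noise).  The restart with the
highest final likelihood wins; ties break toward the lowest restart index.
Defaults: 5 restarts, 200 iterations.  The heavier pipeline runs (1000-row
fits inside 10-fold CV) use 2 restarts and 80–100 iterations — chosen as
the package's standard configuration for these problem sizes; the recovery
results are insensitive to more restarts.

**Numerical policy.**  All solves use the lower Cholesky factor of
K + σ_n²I.  If factorization fails, a diagonal jitter of
1e-10 · trace(K+σ_n²I)/n is added and escalated tenfold up to a 1e-4
multiplier before erroring.  The jitter used is stored in the model export
so the factor is reproducible bitwise.  Likelihood gradients use the trace
identity ∂lml/∂θ = ½ tr((ααᵀ − K⁻¹) ∂K/∂θ) with per-dimension pairwise
squared-difference matrices precomputed per fit.

**Prediction determinism.**  Map prediction is chunked for memory; to make
results independent of chunk size the mean is computed with a fixed
per-row summation order (einsum, not a blocked GEMV/GEMM) and the
triangular solve always takes the multi-column BLAS path (single-point
chunks are padded).  Chunk sizes 1 and 4096 produce bitwise-identical
rasters, which the tests assert.

**Uncertainty convention.**  The reported σ is the latent-function
(epistemic) standard deviation √max(0, k** − vᵀv), de-standardized — model
uncertainty from data scarcity.  Observation noise is *not* added unless
`include_noise=True` is passed; σ maps therefore describe where the model
extrapolates, not the expected scatter of new observations.

## Predictor schema

Thirteen predictors: LAI plus twelve climate variables (SW; TS and SWC at
three depths; H; LE; P; TA; WS), with units, valid ranges and marginal
distribution families fixed in `fluxgpr.schema`.  Vapour-pressure deficit is
observed at towers but is not among the gridded upscaling inputs, so it is
not part of the default schema; all module contracts use `schema.D`, never a
literal, so alternative schemas are a one-line change.  Towers lacking
deeper soil measurements have depths 2–3 filled by copying the deepest
available value (a monotone-profile assumption), with a fill flag on the
record.

NEE is stored positive = atmosphere→biosphere (uptake) everywhere in the
package; the tower reader can flip micrometeorological-convention files on
ingest, and gridded consistency checks refuse to mix sign tags.

## Synthetic test bed

The generator emulates the statistical structure the analysis assumes,
not any particular place or year:

* **Marginals**: each predictor's family (exponential, uniform, chi-square
  with df 5, gamma with shape 2) is scaled so the support starts at the
  valid minimum and ~99.5% of untruncated mass lies below the valid
  maximum; sampling maps a Gaussian copula through the range-truncated
  quantile function, so truncation is exact and values never leave the
  valid range.
* **Dependence**: a hand-set copula correlation matrix (temperatures
  coherent with each other and radiation, soil depths vertically coherent,
  moisture tracking precipitation), projected to the nearest
  positive-definite correlation matrix.  Independent predictors would make
  relevance ranking trivially easy.
* **Fluxes**: GPP = g_max(1−e^(−k_L·LAI)) · SW/(SW+S_half) · w(SWC₁) ·
  t(TA), RECO = r_b·Q10^((TS₁−T_ref)/10) + f_g·GPP, NEE = GPP − RECO, each
  plus Gaussian noise.  Defaults (g_max 30, k_L 0.5, S_half 100 W m⁻²,
  W_half 15 %, T_opt 20 °C, T_width 12 °C, r_b 2, Q10 2, T_ref 15 °C,
  f_g 0.25) give tower-scale flux magnitudes and the expected
  monotonicities (GPP↑SW, RECO↑TS).  Default noise (GPP 0.24, RECO 0.095,
  NEE 0.17 μmol m⁻² s⁻¹) is 10% of the noise-free signal standard
  deviation under these defaults, measured once on a large sample and
  frozen.
* **Scenes**: smoothed Gaussian random fields modulated by a categorical
  vegetation mosaic and a shared seasonal cycle; LAI on a fine grid,
  climate block-averaged to an integer-ratio coarser grid.  Ground-truth
  fluxes are computed noise-free on the *co-registered* fine grid (climate
  bilinearly upsampled — the same co-registration the pipeline performs),
  so closed-loop error isolates the regression, not the resampler.
  Unlike tower tables, scenes deliberately push a small fraction
  (default 5% margin on LAI and TA) of pixels beyond the valid range, to
  exercise the clamp-and-flag path and the σ inflation expected when
  satellite inputs leave the training domain.

What passing closed-loop tests shows: the pipeline recovers a known
nonlinear flux surface from noisy samples of itself, end to end, including
uncertainty behaviour under extrapolation.  What it does not show: skill on
real towers — real data carry measurement-footprint mismatch, gap-filling
artifacts, LAI/PAI/GAI inconsistencies across sites, snow-contaminated
satellite LAI, and reanalysis biases, none of which the generator models.

## Gridded conventions

* Pixel-center registration on north-up, row-major grids; `(x0, y0)` is the
  outer corner of the top-left pixel; half-open pixel extents.  Used
  identically by resampling, tower-pixel extraction, and regional means.
* 8-day composites are anchored at January 1; a 365-day year yields 46
  windows, the last of 5 days (6 in leap years).  Windows with fewer than
  `min_valid_days` (default 4, or the window length if shorter) valid days
  are masked.
* Bilinear resampling is mask-aware (invalid neighbours get zero weight and
  the remainder renormalizes; all-invalid targets are masked) and
  extrapolates as a constant beyond the outermost pixel centers.  Nearest
  is used for categorical maps.
* Annual totals are day-weighted mean fluxes converted with the molar mass
  of carbon (12.011 g mol⁻¹): 1 μmol m⁻² s⁻¹ sustained for 365 days is
  12.011e-6 · 86400 · 365 ≈ 378.78 gC m⁻² y⁻¹.  Annual σ is the
  day-weighted root-mean-square of composite σ — a deliberate upper-bound
  convention (it ignores temporal error cancellation), not a calibrated
  interval.
* Out-of-range pixels are clamped to the schema range and counted in a flag
  raster by default; masking is available but hides exactly the
  extrapolation behaviour the σ layer is meant to expose.
* Intercomparison always regrids fine→coarse by area-weighted block mean
  before computing per-pixel temporal Pearson R and rmse; pixels with fewer
  than 3 common composites are masked; global medians summarize the maps.

## Validation metrics and folds

R² is the coefficient of determination 1 − SS_res/SS_tot (squared Pearson
correlation is reported alongside; the two coincide only for affine
recalibrations).  nrmse is rmse as a percent of the observed range, chosen
to pair with the schema's published ranges; a mean-normalized variant is
selectable.  Fold plans are exact balanced partitions via a deal-around
scheme — for n = 1369 and k = 10 this gives nine folds of 137 and one of
136 (train sides 1232/1233); a historically reported 1232/136 split does
not sum to 1369 and is flagged in the audit rather than reproduced.
Stratification by vegetation class is the default (class imbalance is
real); grouping by site to control leakage is available but unclaimed, as
is a 3×3-pixel tower footprint option and a deseasonalized-anomaly mode for
the correlation analysis.

## Relevance scaling

The polar-plot relevance score is the inverse lengthscale on standardized
inputs, normalized to max 1 — units cancel, ties share a score, and the
ordering is strictly decreasing in lengthscale.  A log-inverse variant is
selectable for models with extreme lengthscale ratios.  Correlation heat
maps report coefficients only; no significance testing or multiplicity
correction is applied, matching how such tables are read.

## Known limitations

* Exact GP: O(n³) training; fine for the ~1e3-sample tower regime, no
  sparse approximations for much larger archives.
* One model per flux; no multi-output coupling, so GPP/RECO/NEE coherence
  is a diagnostic (the consistency check), not a constraint.
* No CRS reprojection (inputs must share a CRS) and no cloud/snow
  screening of satellite LAI.
* The TIFF path stores float32 payloads with georeferencing in a JSON
  ImageDescription tag readable by this package and standard TIFF tools;
  NetCDF (float64, bitwise round trip) is the primary interchange format.
* The kernel is the standard stationary ARD-RBF; relevance rankings
  reflect lengthscales of that stationary model, not any directional or
  non-stationary response.
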