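# Methods

`uavpheno` implements a UAV-based individual-plant phenotyping pipeline for
row-sown crops (the default geometry matches heading vegetables such as
Chinese cabbage on a 45 cm x 65 cm sowing grid): per-flight plant detections
are consolidated into one georeferenced box per plant, per-plant 4-D image
stacks (time point x layer x row x col) are cut from RGB, multispectral (MS)
and plant-height rasters, filtered and summarized into features, and harvest
weight is predicted from single-date or cumulative multi-temporal feature
sets. This note documents the model, the main design choices, the synthetic
data generator, and what the tests do and do not show.

## Detection consolidation and grid assignment

Detector rectangles from all flights are grouped by pairwise overlap and each
group replaced by its coordinate-wise envelope. Design choices where the
procedure is underdetermined:

- **Overlap denominator.** "Intersection greater than 40%" needs a
  denominator; we use intersection / min(area_a, area_b). Early-season boxes
  are several times smaller than late-season ones; normalizing by the smaller
  box makes the criterion scale-robust, whereas IoU would fail to link a
  seedling box nested inside a mature box.
- **Grouping closure.** Groups are connected components of the pairwise
  relation (transitive closure): a chain of flights A-B-C must merge even if
  A and C barely overlap directly.
- **Conflict rule.** Each grid point proposes its nearest box center within
  0.45 m (the within-row plant spacing, Euclidean distance between point and
  box center). A box is claimed by at most one point; the globally nearest
  point wins and the loser stays unassigned rather than cascading to its
  second choice.
- **Pixel convention.** 0-based indices, half-open intervals, row axis
  southward, geotransform anchored at the upper-left corner.

Detection accuracy is assigned plants / plants sown.

## Rasters, registration and stacks

- **Height rasterization** bins point-cloud returns to the grid by per-cell
  mean and fills empty cells by nearest-neighbour from filled ones. Canopy
  height subtracts the first-flight surface raster per pixel (the first
  flight, before canopy closure, serves as the ground reference); negative
  differences are clamped to zero so soil noise cannot produce negative
  volume.
- **MS-to-RGB registration** estimates an integer translation by phase
  cross-correlation between the MS NIR band (provisionally resampled to the
  RGB grid) and the RGB luminance (0.299 R + 0.587 G + 0.114 B), absorbs it
  into the MS geotransform, and resamples all MS bands to the RGB grid by
  nearest-neighbour (each target cell takes the value of the source cell
  containing its center). The correlation peak is located on the *magnitude*
  of the inverse-transformed cross-power spectrum: vegetation is bright in
  NIR but dark in visible luminance, and contrast inversion flips the sign
  of the peak while leaving its location unchanged. Sub-pixel refinement is
  omitted; at 1 cm ground sampling distance, residual co-registration error
  of a few millimetres is below one pixel. Wrap-around shifts are resolved
  to (-N/2, N/2].
- **Stack cutting** uses the smallest half-open pixel window covering the
  merged box, identical across layers and flights; the pixel ground area
  (cm^2) is carried on the stack for the volume feature.
- Stacks are in-memory xarray-compatible arrays; no on-disk stack format is
  provided (rasters persist as GeoTIFF, detections/grids as GeoJSON, tables
  as CSV).

## Vegetation indices and the noise-filter cascade

Eleven indices are registered: GRVI, MGRVI and RGBVI in RGB-camera and MS
variants, plus GNDVI, NDRE, NDVI, RECI and SAVI from the MS bands. Pruning
of correlated indices (|Pearson r| > 0.95 on the plants x index median
table) is greedy in a frozen order — RGB variants first, then MS, each in
registry order — because the surviving set depends on traversal order;
constant columns are retained and flagged since their correlation is
undefined.

The three-stage cascade:

1. **Soil mask**: 2-cluster k-means (k-means++ init, 10 restarts, fixed
   seed) on per-pixel vectors of the retained indices; the cluster with the
   lower mean NDVI is soil. Labeling by NDVI, not by cluster index, makes
   the decision invariant to centroid initialization.
2. **Contour filter**: 8-connected components of the vegetation mask below
   5% of the largest component's area are removed (the threshold is
   relative because plant area grows by two orders of magnitude over the
   season). This deletes slivers of neighbouring plants that enter the
   padded window.
3. **Histogram equalization** of the RGB layers only, with the plain
   mapping v' = round(255 * cdf(v)) on a 256-level scale, applied before the
   RGB medians are taken. MS bands and indices are summarized from raw
   reflectances.

The cascade wrapper adds a **separability guard**: the low-NDVI cluster is
discarded only when the between-cluster NDVI gap exceeds 4x the pooled
within-cluster NDVI standard deviation. A forced 2-means split of a single
homogeneous population produces a gap of about 2.7 pooled SDs, while genuine
soil/vegetation contrast in these data is an order of magnitude larger; the
guard therefore makes the cascade idempotent (re-running it on an already
soil-free window removes nothing) without affecting genuinely mixed windows.

**Centering and cropping.** The convex hull of the first-flight vegetation
mask defines the plant center (mean of hull vertices, a degenerate hull
falls back to the pixel mean); all layers of all flights are shifted by the
same whole-pixel translation so this center lands on the window center, then
the central 70% of each dimension is retained ("reduced by 70%" is read as
*retain* 70%; removing 70% would truncate mature plants). The pipeline pads
each merged box by (1/0.7 - 1)/2 per side before cutting so the final crop
returns a field of view equal to the detected box.

## Features

Per plant and flight: medians of the 3 RGB (post-equalization) and 5 MS
layers; medians of the retained indices; and three canopy-geometry features
from the height image over the vegetation mask — PH (90th percentile with
linear quantile interpolation), leaf angle, and volume = sum of pixel
heights (cm) x pixel area (cm^2). The per-pixel leaf angle is the angle
between (dx, dy, H) — from the window center anchored on the ground plane to
the pixel's canopy surface, in-plane offsets in the same length unit as the
heights — and the vertical; one angle per pixel is aggregated by the
*median* (robust, and the procedure defines a per-pixel angle but reports a
single feature). Zero-length vectors are excluded. Standardization is
z-scoring with training-row statistics only (per split or fold), stored for
the inverse transform; it is never fitted on held-out rows.

## Weight prediction

90/10 train/test split (test size floored), five model families — PLS,
lasso, ridge, linear-kernel SVR, random forest — each tuned by exhaustive
grid search under five-fold CV (seeded shuffled folds, no stratification;
scaler fitted inside each fold) and refitted on all training rows. Grids:
lasso/ridge penalty on a 13-point log grid 1e-3..1e3; PLS components
1..min(20, p); SVR cost on 7 points 1e-2..1e2 with epsilon 0.1; RF with 500
trees, max_features in {ceil(p/3), ceil(sqrt(p))} and min leaf in {1, 5} —
standard ranges spanning weak to strong regularization.

Metrics: R^2 = 1 - SS_res/SS_tot and RMSE = sqrt(mean((y - y_hat)^2)), in
g/plant.

Feature selection: exhaustive subset search (capped at 15 features, every
non-empty subset scored by mean CV R^2 with a lightly regularized lasso,
alpha = 1e-3 after standardization, so the wrapper scorer is nearly
unbiased but still well-posed); greedy sequential forward selection with
the same scorer (implemented directly so the full selection path, with its
prefix property, is returned); and random-forest mean-decrease-in-impurity
ranking normalized to sum to one.

Temporal schemes: all dates; 7/15/30-day resolutions by a greedy walk from
the first date (taking the earliest date at least N days after the last
selected one — flight calendars are irregular, so exact spacing rarely
exists); and the growth-pattern resolution mapping each anchor in
{12, 34, 56, 80, 101} days after transplanting to the nearest available
date (ties to the earlier). Cumulative designs concatenate all selected
dates up to a cutoff; single-date designs use the cutoff date alone. The
days-prior-to-harvest sweep evaluates every (scheme, cutoff, model) cell on
one fixed split with shared fold assignments, so feature selection and model
assessment see the same resampling.

## Synthetic field generator

The generator defines the study conditions for all end-to-end tests.
Defaults: a 10 x 10 plant grid at 0.45 m x 0.65 m, 1 cm GSD, eight flights
at 12-101 days after transplanting, 5% detector miss rate and 1 cm box-edge
jitter.

- **Canopy**: each plant is a disc of uniform vegetation reflectance with a
  cosine-tapered height profile; radius and apex height follow a logistic
  (rate 0.12/day, midpoint 55 DAT) from seedling size (4 cm / 3 cm) to a
  per-plant maximum. A lognormal vigor factor (sigma 0.18) acts as g^0.5 on
  radius and g^2 on height, so volume scales roughly as g^3 (volume CV near
  0.6). Radii are capped at 95% of half the minimum spacing; a configured
  maximum radius above half the spacing is rejected outright.
- **Spectra**: vegetation NIR 0.80 vs soil 0.25 and red 0.12 vs 0.30 give
  the NDVI contrast the k-means mask must find. A per-plant chlorophyll
  factor (lognormal, sigma 0.35) modulates MS red through a Gaussian bump
  (width 12 days) centered on the growth midpoint, so the spectral signal a
  plant's weight depends on is visible in mid-season flights but absent from
  the final one — cumulative multi-temporal designs are therefore strictly
  more informative than the final date alone. All bands carry additive
  Gaussian pixel noise (sd 0.01) and are quantized to 1e-4 reflectance so
  the integer-scaled GeoTIFFs round-trip losslessly.
- **Weights**: weight_i = 0.125 g/cm^3 x final volume + 1800 g x mean
  mid-season NDVI + N(0, 80 g), truncated at 1 g, where volume and NDVI are
  computed from the *rendered* rasters over the plant's support. The
  coefficients give a mean near 2850 g and SD near 900 g per plant,
  comparable to field-grown Chinese cabbage. Because the truth is defined
  on the rendered imagery, an ordinary least-squares fit of weight on
  (volume, NDVI) recomputed from the emitted rasters recovers both
  coefficients exactly when the weight noise is off.
- **Determinism**: all randomness flows from one seeded generator in a fixed
  draw order; identical configs produce bit-identical bundles. Detection
  replicates use a per-flight child seed.

What the generator does *not* emulate: photorealistic texture, shadows and
specular brightness, structure-from-motion reconstruction error, detector
confidence scores, plant-shape asymmetry, and occlusion between neighbours
beyond simple window overlap. Passing end-to-end tests therefore show the
pipeline's bookkeeping, geometry and statistics are correct under known
ground truth — not that the reported accuracies transfer to real imagery.

## Numerical choices and degenerate inputs

- Phase correlation raises on constant images (undefined phase); shifts are
  integers; peaks are located on the correlation magnitude.
- Index cells with zero denominators become missing and are excluded from
  medians; fully masked windows yield missing features, and rows with
  missing cells are dropped (and counted) when a design matrix is built.
- Zero-variance targets and zero-SD feature columns raise with the column
  named rather than silently producing NaN.
- Quantiles use linear interpolation between order statistics; medians of
  even counts average the two central values.
- Problem sizes in the tests and the acceptance script (10 x 10 plants,
  eight flights, 64 x 64 registration tiles, 20-replicate selection studies)
  were chosen as the smallest sizes at which every estimator is exercised in
  its intended regime.

## Known limitations

- Integer-pixel registration only; at coarser GSDs sub-pixel refinement
  would be needed.
- The separability guard's factor of 4 is calibrated for 2-means splits; a
  k > 2 soil model would need its own rule.
- The greedy interval scheme depends on the calendar's first date; an
  anchor-based variant would select differently on sparse calendars.
- Exhaustive selection is exponential and deliberately capped at 15
  features.
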