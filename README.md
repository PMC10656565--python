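# uavpheno

Individual-plant phenotyping from UAV time series, for field scientists who
fly a plot repeatedly (RGB + multispectral cameras, photogrammetric height)
and want per-plant growth features and harvest-weight predictions.

Given per-flight plant detections (rectangles), georeferenced rasters and a
sowing-grid specification, the package:

1. **consolidates detections** across flights — boxes whose intersection
   exceeds 40% of the smaller box are grouped transitively and replaced by
   their envelope — and indexes each merged box to the nearest sowing-grid
   point within the plant spacing, by the Euclidean distance
   SPd = sqrt((Pc_x - BBc_x)^2 + (Pc_y - BBc_y)^2);
2. **builds per-plant 4-D image stacks** (time point x layer x row x col):
   plant height from point clouds minus the first-flight surface,
   multispectral bands co-registered to the RGB grid by phase
   cross-correlation plus nearest-neighbour resampling;
3. **filters and summarizes** each stack: vegetation indices (GRVI, MGRVI,
   RGBVI, GNDVI, NDRE, NDVI, RECI, SAVI; e.g. NDVI = (NIR - red)/(NIR + red)),
   pruning at |r| > 0.95, a k-means soil mask, a contour area filter, RGB
   histogram equalization, convex-hull centering with a 70% crop; then per
   flight the layer and index medians, the 90th-percentile plant height, an
   aggregate leaf angle (cos angle = P_p . V_c / ||P_p|| ||V_c||) and the
   canopy volume (sum_i H_i * a_p, cm^3);
4. **predicts harvest weight** with PLS, lasso, ridge, linear SVR and random
   forest under five-fold cross-validation on a 90/10 split, with exhaustive
   / sequential-forward / RF-importance feature selection, five
   temporal-resolution schemes, single-date vs cumulative designs, and a
   days-prior-to-harvest sweep; accuracy as R^2 = 1 - SS_res/SS_tot and
   RMSE (g/plant).

A synthetic-field generator (`uavpheno.synthetic_field`) renders a complete
campaign — rasters, detections, grid and a per-plant truth table whose
weights follow a known linear model of final canopy volume and mid-season
NDVI — so the entire pipeline is testable end to end with known ground
truth.

## Worked example

```python
from uavpheno.synthetic_field import FieldConfig, generate_field
from uavpheno.pipeline import extract_feature_table
from uavpheno.weight_modeling import (ModelSpec, TemporalScheme,
                                      build_design, cross_validate, split_data)

bundle = generate_field(FieldConfig(seed=11))      # 10x10 plants, 8 flights
result = extract_feature_table(bundle, seed=0)
print(f"detection accuracy: {result.detection_accuracy:.3f}")
print(f"feature table: {result.table.data.shape}")

train, test = split_data(result.table, seed=0)
scheme = TemporalScheme("all_tps", mode="cumulative", cutoff_dat=101)
X, y = build_design(train, scheme)
fit = cross_validate(ModelSpec("lasso", seed=0), X, y)
fit.evaluate(*build_design(test, scheme))
print(f"lasso: mean CV R^2 {fit.mean_cv_r2:.3f}, "
      f"held-out R^2 {fit.test_r2:.3f}, RMSE {fit.test_rmse:.0f} g/plant")
```

Output:

```
detection accuracy: 1.000
feature table: (100, 104)
lasso: mean CV R^2 0.987, held-out R^2 0.993, RMSE 86 g/plant
```

All 100 plants are recovered (a 5% per-flight detector miss rate is healed by
merging across eight flights), the table holds 13 features x 8 flight dates
per plant, and the cumulative multi-temporal lasso explains 99% of held-out
weight variance on this synthetic field — the weights are generated from
canopy volume and mid-season NDVI, both of which the features capture.

There is also a CLI mirroring these stages:

```bash
uavpheno synth --out field/ --seed 11
uavpheno features field/ --out-features features.csv --out-weights weights.csv
uavpheno sweep features.csv weights.csv --out results.csv --harvest-dat 106
```

## Layout

- `src/uavpheno/synthetic_field.py` — synthetic campaign generator
- `src/uavpheno/plant_geolocation.py` — box merging and grid assignment
- `src/uavpheno/raster_processing.py` — height rasters, registration, stacks
- `src/uavpheno/plant_imaging.py` — indices, filter cascade, centering
- `src/uavpheno/phenotype_features.py` — feature summarization, tables
- `src/uavpheno/weight_modeling.py` — selection, regressors, schemes, sweeps
- `src/uavpheno/pipeline.py` — end-to-end orchestration
- `docs/methods.md` — models, assumptions, design choices, limitations
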