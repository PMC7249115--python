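# rarefynet

Refinement of decametric satellite NDVI maps of row crops using a single
high-resolution, canopy-masked reference map.

## The problem

NDVI from freely available decametric satellite imagery (e.g. the 10 m
red/NIR bands) is a workhorse of precision agriculture, but in vineyards
and orchards every coarse pixel mixes vine canopy with inter-row soil and
weeds.  The mixed-pixel value

    x_raw = f * NDVI_canopy + (1 - f) * NDVI_soil + b

(f = canopy cover fraction, b = radiometric bias) both under-reads vigor
and carries a vigor-independent soil/weed signal, so raw satellite maps can
fail to separate the management zones an agronomist cares about.  A
canopy-masked NDVI map from one centimetre-scale UAV survey, downsampled to
the satellite grid, is a far better proxy for canopy state — but UAV
flights are expensive to repeat.

`rarefynet` trains a light-weight residual-inception network (17,342
parameters) on a *single* co-registered (satellite, UAV reference) map
pair, learning `y_hat_i = F(X_i; Theta)` where `X_i` is a 3x3x2 tensor
holding each pixel's NDVI neighbourhood and grid location.  Once trained,
it refines satellite maps from any other acquisition date.  The package
also ships the downstream tooling: a K-means (k-means++/Elkan, 15
restarts, lowest-WCSS) three-class vigor classifier, one-way ANOVA and
Pearson validation statistics, and a synthetic vineyard scene generator so
the whole pipeline runs and is tested without any external data.  See
`docs/methods.md` for the model, training protocol and generator details.

Note: no deep-learning framework is required — the network, including
backpropagation and the AdamW optimizer (Adam with decoupled weight
decay), is implemented in NumPy and trains in minutes on one CPU core.

## Worked example

```python
from rarefynet import (SceneConfig, generate_scene, scene_maps,
                       pair_datasets, split_train_test, build_model,
                       train, TrainConfig, classify_vigor, evaluate_refinement)
from rarefynet.cli import refine_map, run_pipeline

metrics = run_pipeline(seed=1)          # simulate -> train -> refine -> validate
for key in ("rmse_raw_transfer", "rmse_refined_transfer",
            "pearson_raw_transfer", "pearson_refined_transfer",
            "anova_f_raw_transfer", "anova_f_refined_transfer"):
    print(key, round(metrics[key], 4))
```

prints (seed 1):

```
rmse_raw_transfer 0.3645
rmse_refined_transfer 0.0959
pearson_raw_transfer 0.7821
pearson_refined_transfer 0.8193
anova_f_raw_transfer 804.9884
anova_f_refined_transfer 1042.5196
```

Reading these numbers: the raw satellite map disagrees with the canopy-only
reference by 0.36 NDVI RMSE (the mixed-pixel bias dominates); after
training on one scene and refining a *second* scene with the same layout,
the disagreement drops to 0.096 — a 74% reduction — while the Pearson
correlation with the reference rises.  Grouping each map's pixels by the
latent vigor zones, the one-way ANOVA F statistic of the refined map
(1042) exceeds that of the raw map (805): the refinement sharpens, rather
than blurs, the agronomic signal.

The same workflow is available from the shell:

```bash
rarefynet simulate --seed 0 --out scene/
rarefynet train --sat scene/xraw.tif --uav scene/yuav.tif --seed 0 --out fit/
rarefynet refine --checkpoint fit/checkpoint.npz --sat scene/xraw.tif --out refined.tif
rarefynet classify --input refined.tif --out vigor.tif
rarefynet validate --raw scene/xraw.tif --refined refined.tif \
                   --reference scene/yuav.tif --out report.csv
```

All rasters are single-band float32 GeoTIFFs with nodata and geo tags;
every command writes a JSON run manifest for reproducibility.

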