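# Methods

## Problem

Decametric satellite pixels over row crops (vineyards, orchards) mix vine
canopy with inter-row soil and weed vegetation.  NDVI computed from such
mixed pixels under-reads canopy vigor and is contaminated by a
vigor-independent soil/weed signal, so raw satellite NDVI maps can fail to
separate agronomic vigor zones.  A canopy-masked NDVI map derived from a
single high-resolution (centimetre-scale) UAV survey, downsampled to the
satellite grid, is far closer to the true canopy signal.  This package
learns the mapping from raw satellite pixels to that canopy-only reference
from one co-registered map pair, and then applies it to satellite
acquisitions from other dates.

## Refinement model

Each map pixel x_i is presented to the network as a 3x3x2 tensor: layer 0
is the 3x3 NDVI neighbourhood (zero-padded at raster boundaries), layer 1
the row-major linear indices of the nine cells.  The location layer is
normalised by 1/(pixel_count - 1) so both layers occupy comparable ranges
(a documented toggle restores raw indices); padded cells are zero in both
layers.  The refined pixel is

    y_hat_i = F(X_i; Theta)

with F a stack of two inception blocks, global average pooling, and a small
dense head with a residual connection to the raw centre pixel:

* **Block 1** (input 2 channels, 8 maps/branch, concat width 32) —
  branches: 1x1 channel-halving bottleneck + 3x3 conv; 3x3 conv; 3x3 conv
  with dilation 2 (atrous, looking past the immediate neighbours); 1x1
  conv.  Every branch ends in batch normalisation then ELU.
* **Block 2** (input 32 channels, 32 maps/branch, concat width 128) —
  branches: bottleneck + 3x3; bottleneck + 3x3 dilation 2; 1x1 conv; 3x3
  average pool + 1x1 conv.  The 1x1 bottlenecks in front of the expensive
  f>1 convolutions and the pooling branch keep the model at **17,342
  trainable parameters**; without them the same widths would cost ~30k.
  This is the published design intent (a light-weight model of order 16k
  parameters) and the band the acceptance check enforces; the exact
  per-branch kernel/dilation assignment is configurable (`BranchSpec`).
* **Head** — GAP, dense(32)+ELU, dropout p=0.2, dense(1)+ELU producing a
  correction that is **added to the raw centre NDVI**, then a final
  1-weight ReLU unit that removes any residual offset between the satellite
  and reference radiometric spaces and clamps the output non-negative.

The residual connection means the trunk only learns the refinement (the
inter-row contamination to remove), not the NDVI value itself.  The final
unit is initialised at identity (w=1, b=0): a random negative weight there
would close the output ReLU for every input and zero all gradients at the
first step.  Convolutions use He-normal initialisation, dense layers
Glorot-uniform, all driven by one seeded generator so builds are
bit-reproducible.  Zero padding (width = dilation x f//2) keeps every
branch output 3x3.

Spatial convolutions are evaluated as a single GEMM over an im2col patch
matrix; training arithmetic is float32 (float64 available for gradient
checking, which validates backpropagation against central finite
differences).

## Training

Loss is the batch RMSE, L = sqrt(1/m * sum (y_hat - y)^2).  Optimisation is
AdamW — bias-corrected Adam plus decoupled weight decay,

    theta <- theta - eta * m_hat / (sqrt(v_hat) + eps) - eta * alpha * theta

with defaults eta = 5e-4 (constant; no schedules), batch 64, 300 epochs,
beta = (0.9, 0.999), eps = 1e-8, alpha = 1e-4.  Each training sample is
augmented by rotating the 8-cell ring of both tensor layers around the
fixed centre: all 7 distinct nonzero cyclic steps by default (configurable
down, since the useful number of rotations depends on how anisotropic the
scene is).  The test partition (30% by default, random split; a row-blocked
split is provided) is never augmented.  Divergence (non-finite loss or
gradient) aborts training and restores the last completed epoch.  A
learning-rate range test (exponential sweep, smoothed-loss divergence
detection, suggestion one decade below the divergence point) and a
random-then-grid hyperparameter search on a 10% subset are provided for
tuning; the defaults above were fixed without per-run tuning.

## Vigor classification

Three management classes (L/M/H) come from K-means on the 1-D NDVI values
of each map, fitted per map (class boundaries are intentionally not shared
across maps).  Each fit runs 15 k-means++/Elkan restarts (scikit-learn's
solver; Elkan and Lloyd share fixed points) with max 500 iterations and
tolerance 1e-4, keeping the lowest-WCSS restart; the per-restart WCSS log
and winning restart index are part of the result.  Classes are relabelled
so centroid NDVI is ascending; nearest-centroid ties resolve to the lower
class.  scikit-learn's conventions apply for empty-cluster re-seeding and
its tolerance is scaled by data variance; tests verify the fixed-point and
restart contracts against an independent Lloyd implementation.

## Validation statistics

One-way fixed-effects ANOVA of map pixels grouped by vigor class uses the
definitional sums (SS_classes = sum n_j (mean_j - grand)^2, SS_error =
within-group squares; F = MS_classes/MS_error with (g-1, n-g) degrees of
freedom; p from the F survival function, scipy).  A zero error mean square
reports F = +inf, p = 0.  Pearson correlation uses scipy's product-moment
estimator; correlating two class maps encodes L/M/H as ordinals 0/1/2.
Published nine-row ANOVA decompositions (three parcels x raw/refined/
reference) serve as regression fixtures for the F and p arithmetic; they
are internally consistent to ~1e-3 relative.

## Synthetic scenes

The generator emulates the statistical structure the method assumes, at
defaults chosen once as vineyard-plausible:

| parameter | default | meaning |
|---|---|---|
| scene | 320 m x 320 m | 32x32 decametric cells (~1k samples) |
| GSD | 0.05 m | UAV-scale ground sample distance |
| cell | 10 m | satellite-scale cell |
| row spacing / canopy width | 2.7 m / 1.1 m | canopy fraction ~0.41 |
| row azimuth | 15 deg | rows oblique to the grid |
| canopy NDVI means | 0.45 / 0.65 / 0.85 | three vigor levels |
| sigma_canopy / sigma_soil | 0.05 / 0.03 | per-pixel noise |
| soil NDVI | 0.15 | bare inter-row mean |
| weed_sigma / correlation | 0.08 / 0.7 cells | inter-row vegetation field |
| sigma_sat / offset | 0.02 / -0.05 | sensor noise, radiometric bias |

The vigor field is a thresholded low-frequency Gaussian field on the cell
grid (correlation ~3 cells, equal-area thresholds), giving three spatially
coherent zones.  Row geometry is rasterised analytically (distance across
rows modulo spacing).  The inter-row **weed field** — a smooth,
vigor-independent NDVI signal added to soil pixels — is essential realism:
without it the raw satellite map would be an affine image of the reference
and statistical refinement would be trivial; with it the raw map carries
structured contamination that only the neighbourhood context can suppress,
which is precisely the situation the method targets.  The UAV-style
reference is the canopy-masked per-cell mean (nodata where a cell has no
canopy); the satellite-style raw map is the all-pixel mean plus Gaussian
sensor noise and a radiometric offset, clipped to [-1, 1].  With all noise
off the raw cell equals fraction*canopy + (1-fraction)*soil + offset
exactly (checked to 1e-12).  Decametric grids of the two maps coincide; a
configurable sub-cell shift exists for misregistration experiments.

What the generator does **not** model: slope illumination and shadowing,
atmospheric residuals, phenology between acquisition dates, co-registration
error by default, or non-Gaussian sensor noise.  Passing tests therefore
demonstrate the machinery and its statistical behaviour under the stated
assumptions, not performance on any particular real sensor pair.

## Experiment sizes and determinism

The end-to-end experiment trains on one scene (70/30 split of ~1,024
cells, ~717 training tensors, 7 ring rotations, 300 epochs) and evaluates
on a second scene generated with the same configuration but a different
seed — the temporal-transfer analogue.  These sizes keep a full run to a
few minutes on one CPU while matching the scale of a realistic single-field
campaign.  All randomness (scene, split, initialisation, dropout,
shuffling, clustering restarts) derives from per-purpose generators spawned
from one seed; single-threaded runs are bit-reproducible.

## Known limitations

* The network refines per pixel from a 3x3 context; contamination
  correlated over much larger scales than a cell is indistinguishable from
  vigor signal and is not corrected.
* K-means on 1-D NDVI assumes three separable modes; maps with fewer than
  three distinct values are rejected rather than force-fitted.
* The GeoTIFF I/O writes plain north-up single-band float32 rasters with
  pixel-scale/tiepoint and nodata tags; reprojection and CRS handling are
  out of scope.
* ANOVA assumes independent pixels within groups; spatial autocorrelation
  inflates the effective F, so p-values on smooth maps are optimistic (as
  they are in the standard practice this mirrors).
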