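# Methods

`obforest` implements an object-based, multi-temporal mapping workflow for
forest cover and forest subtypes from 30 m, 4-band (blue, green, red, NIR)
surface-reflectance imagery: spectral/phenology features, two-level
multiresolution segmentation, a hierarchical threshold decision tree with
elevation rules, stratified accuracy estimation, and cross-product map
comparison. This note records the models, parameter choices and numerical
conventions, and what the synthetic experiments do and do not demonstrate.

## Spectral features

Per-date indices on reflectance bands B1..B4:

```
NDVI = (B4 - B3)/(B4 + B3)        NDWI = (B2 - B4)/(B2 + B4)
RVI  = B4/B3                      EVI  = 2.5 (B4 - B3)/(B4 + 6 B3 - 7.5 B1 + 1)
```

Zero denominators are masked rather than propagated as infinities so that
all downstream thresholding is total. EVI is computed on reflectance and is
not clipped (it is unbounded by construction). NDVI and NDWI are bounded in
[-1, 1] for nonnegative reflectance, and RVI = (1 + NDVI)/(1 - NDVI)
wherever both are defined; both facts are property-tested.

The LBV transform summarises a 4-band spectrum as a radiance level L, a
visible-infrared balance B and a band-variation magnitude V. The
coefficients are configurable (a 3x4 matrix); the shipped default is

```
L = (B1 + B2 + B3 + B4)/4
B = B4 - (B1 + B2 + B3)/3
V = || (B2 - B1, B3 - B2, B4 - B3) ||
```

Only the qualitative behaviour of V matters to the classifier — closed
forest canopies have a smoother band-to-band profile (lower V) than
herbaceous vegetation with its strong red edge — and any coefficient set
with that property can be substituted.

Object features are means over member pixels, with two deliberate
exceptions: RVI and B3/B1 are computed as ratios of the object's mean bands
rather than means of per-pixel ratios. A per-pixel reciprocal of a small
band value (blue reflectance of dark canopy, ~0.03) explodes under noise
and biases the object mean arbitrarily; the ratio of means is stable and is
the conventional object feature in OBIA systems.

## Segmentation

Bottom-up region merging from single-pixel objects under the standard
multiresolution criterion: merging objects a and b costs

```
cost    = w_color * dh_color + w_shape * dh_shape
dh_color = sum_k w_k (n_ab s_ab - n_a s_a - n_b s_b)      s = band std dev
dh_shape = w_compact * dh_cmp + w_smooth * dh_smooth
h_cmp    = l / sqrt(n)        h_smooth = l / b
```

(l = exposed-edge perimeter, b = bounding-box perimeter, each dh computed
as n_ab h_ab - n_a h_a - n_b h_b). A merge executes only when cost <
scale^2. Merging follows local mutual best fitting: from each seed object
the chain of best neighbours is walked until two objects are each other's
best partner. Determinism comes from a seeded scan order plus a
lowest-object-id tie-break on equal costs. Objects carry incremental
accumulators (n, per-band sum and sum of squares, perimeter, bbox) and a
region adjacency graph with shared-boundary lengths, so a merge is
O(degree); 4-connectivity throughout.

Defaults follow the two-level design: level 1 (forest vs non-forest
objects) scale 30, shape 0.3, compactness 0.6; level 2 (forest subtypes,
run only inside the level-1 forest mask) scale 10, shape 0.1, compactness
0.6. Band weights default to 1 per plane. The scale threshold is treated as
dimensionless.

Two conventions required a decision:

* **Input planes.** The segmentation input is the 4 bands of every
  available date (so 16 planes for a four-date stack), multiplied by
  `plane_scale` = 100 so reflectance in [0, 1] becomes DN-like units
  commensurate with the published scale values. Multi-date planes give
  materially cleaner boundaries between phenologically distinct but
  spectrally similar classes than any single date; a single growing-season
  date can be configured.
* **Audit.** Every executed merge is logged with its cost, and tests assert
  that all logged costs were below scale^2 and that accumulators agree with
  a from-scratch recomputation off the final label raster. A naive
  reference implementation (explicit pixel sets, costs recomputed
  definitionally at every step) is kept in the test suite and must produce
  identical partitions on small images.

## Decision-tree classification

Level 1, on coarse-object features, in strict order:

1. NDWI(intermediate season) >= a -> water;
2. NDVI(growing season) < b -> non-vegetation, split into settlements vs
   other land by 1-nearest-neighbour on z-standardised multi-date band
   means (standardisation fit on training objects; distance ties resolve to
   the smaller class code);
3. V(growing season) < c AND NDVI(growing season) >= d -> forest
   candidate. The conjunction (rather than a sequential split) is an
   interpretive choice; both cuts are calibrated.
4. remainder -> cropland/grassland/wetland, split by nearest-neighbour on
   per-date NDVI + NDWI trajectories (the workflow's focus is forest; this
   split is a supervised fallback rather than a thresholds tree).

Level 2, on fine-object features within the forest mask:

1. early-spring NDVI >= e -> evergreen (needleleaf by default; the
   evergreen-broadleaf class exists in the scheme but is disabled because
   the mapped region contains no such forest);
2. summer EVI < f -> deciduous needleleaf;
3. summer EVI in [g_low, g_high] AND mean elevation < h(zone) -> mixed
   forest, with h per mountain zone (defaults 1000 m Changbai, 900 m
   Zhangguangcai, 700 m Xiaoxing'an);
4. remainder -> deciduous broadleaf;
5. shrubland extraction from the deciduous-broadleaf/mixed pool:
   B3/B1 >= i AND RVI < j AND mean elevation < k.

### Threshold calibration

Thresholds a-g, i, j are calibrated per node from training samples:
`calibrate_threshold` searches every midpoint between adjacent distinct
values of the pooled groups, minimises training misclassification, breaks
ties toward the larger margin then the lower cut, and records the
direction. An exhaustive-search oracle in the tests confirms the optimum.
Degenerate groups (identical values) are flagged and return a 0.5 error
rate. Any threshold can instead be pinned in the configuration, and every
calibrated value is logged in the run report. g_low is tied to f (the
deciduous-needleleaf cut) so the EVI bands partition.

The elevation limits are the exception: h (mixed forest) and k (shrubland,
default 500 m) are knowledge-based configuration values, not calibrated
cuts. Broadleaf forest occupies low terrain as well, so a trained elevation
cut for shrubland sits flush against the upper edge of the shrub range and
has no margin — in trials it silently demoted boundary-elevation shrubland.
The spectral conditions i and j carry the discrimination; the elevation cap
only vetoes implausible terrain.

Thresholds are calibrated once from the pooled training points of all
zones (zone-wise calibration would starve rare classes), after which each
zone is segmented and classified independently and the zone maps
mosaicked. Which date plays "early spring", "intermediate" and "summer" is
declared in the configuration; there is no attempt to infer it.

## Accuracy estimation

`simple_accuracies` gives count-based UA_i = n_ii/n_i., PA_j = n_jj/n_.j,
OA = tr(n)/n. `area_weighted_accuracies` implements the good-practice
stratified estimator for maps validated with disproportionate samples:
cell proportions p_ij = W_i n_ij / n_i. from mapped-area proportions W_i,
OA = sum p_ii, PA_j = p_jj / p_.j, with

```
SE(UA_i)^2 = UA_i (1-UA_i)/(n_i. - 1)
SE(OA)^2   = sum_i W_i^2 UA_i (1-UA_i)/(n_i. - 1)
SE(PA_j)^2 = [ N_j^2 (1-PA_j)^2 UA_j (1-UA_j)/(n_j. - 1)
             + PA_j^2 sum_{i!=j} N_i^2 q_ij (1-q_ij)/(n_i. - 1) ] / N_hat_j^2
```

and 95% intervals of 1.96 SE. W_i must cover all mapped classes and sum to
1 within 0.01 (printed tables round to two decimals). When W_i is
proportional to n_i. the weighted and simple estimators coincide exactly
(tested), and the analytic SEs agree with a stratified bootstrap within
15% (tested). Full precision is kept internally; rounding happens only in
reporting.

Reproducing the published validation tables from their printed counts
recovers the subtype accuracies (e.g. deciduous-broadleaf UA 0.84,
shrubland PA 0.62, mixed-forest PA 0.69), the 30 m product's forest UA
0.89 +/- 0.02, and the coarse products' weighted PAs (0.58 forest, 0.79
non-forest). The published headline OA of 0.91 and non-forest UA of 0.94
for the 30 m product are *not* recoverable from the printed counts under
either estimator (they compute to ~0.88 and ~0.87 area-weighted); the
package reproduces what the formulas yield and does not fit to the printed
values.

## Map comparison

External categorical products are remapped to the common scheme through
total lookup tables (an unmapped code is an error, not silent nodata),
reduced to binary forest masks, and aggregated to a coarse percentage grid
— default block 50 fine pixels, i.e. 1500 m at 30 m resolution. The coarse
grid anchors at the fine-grid origin; partial edge blocks normalise by
their own valid-pixel count; blocks with no valid pixel are nodata and are
excluded from difference histograms (their count is retained). Differences
between two percentage grids are binned in 10-point classes. Area
summaries multiply pixel counts by pixel_size^2 and report subtype shares
of total forest; per-zone areas sum exactly to whole-map areas.

## Synthetic scenes

The generator emulates the statistical structure the classifier assumes,
not radiometric realism. Each of eleven classes has a monthly 4-band mean
table realising the contrasts the tree exploits: evergreen NDVI >= 0.6
year-round; deciduous forest NDVI <= 0.3 in April rising past 0.7 in July;
summer EVI ordering needleleaf < mixed < broadleaf; forest V below
herbaceous V; water NDWI positive; shrubland with high B3/B1, depressed
RVI and low terrain. Reflectance is the class monthly mean plus i.i.d.
Gaussian noise (default sd 0.02 reflectance units, a plausible
post-atmospheric-correction residual at 30 m), clipped to [0, 1]. Default
scenes use four dates (mid-April, mid-June, mid-July, mid-September),
matching the requirement of at least three acquisitions from spring to
fall.

Landscape geometry is seeded random rectangles (default sides 16-44 px)
stamped on a deciduous-broadleaf background to configured area fractions
(default mix: 52% forest subtypes, 29% herbaceous, 19%
water/settlements/bare), with a persistent patch-size back-off so targets
are met even on crowded canvases. The DEM is a smooth west-east ramp
(200-1100 m) with sinusoidal relief. Mixed-forest and shrubland patches
are constrained to terrain below 650 m and 450 m respectively — without
that structure the elevation rules would be untestable vacuously or wrong
by construction. Sample points are drawn uniformly without replacement per
class and split into training/validation roles.

What the synthetic results do show: exact recovery of all patch interiors
at zero noise; >= 0.95 held-out overall accuracy and >= 0.9 per-subtype
producer's accuracy at noise sd 0.02 (seed-pinned); correct behaviour of
the zone-specific elevation limits. What they do not show: robustness to
spatially correlated noise, mixed pixels, clouds, topographic illumination,
within-class phenological variability, or label noise in field points —
all absent from the generator. Accuracy on real imagery will be lower.

Boundary pixels deserve a caveat: with hard patch edges and i.i.d. noise,
single-pixel merge costs are noise-dominated, so object borders wander a
pixel or two and objects straddling a class edge inherit intermediate
features. Validation points on such borders are the residual error mode in
noisy runs; interiors classify essentially perfectly.

## Numerical conventions

* Grids are north-up, 0-based row/column, pixel-center; point-in-pixel
  lookup by containing cell; pixel area = pixel_size^2.
* Reflectance is float with a boolean validity mask; no numeric sentinel
  values. Masking any band of a date masks the date's pixel.
* Variances inside segmentation are population (1/n) moments computed from
  running sums; tiny negative round-off is clamped to zero before the
  square root.
* All stochastic steps (scene synthesis, sampling, segmentation scan
  order) take explicit seeds; identical seeds give bit-identical outputs.
* Problem sizes in the shipped experiments: the reference run is a
  512 x 512, four-date scene (~0.26 Mpixel, about two to three minutes end
  to end on one core); unit and property tests use 8 x 8 to 256 x 256
  instances.

## Known limitations

* Segmentation is a greedy local optimiser; the scale-monotonicity of
  object counts is an empirical property of the criterion, not a theorem,
  and is asserted on fixed test images only.
* The non-forest vegetation split (cropland/grassland/wetland) is a
  nearest-neighbour fallback, not a calibrated tree; its skill rests
  entirely on the training sample.
* The evergreen branch cannot distinguish needleleaf from broadleaf
  evergreens; the latter class is disabled by default.
* CRS handling is a pass-through tag; inputs must be pre-registered to a
  common grid. No resampling, reprojection or atmospheric correction is
  provided.
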