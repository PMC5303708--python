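# Methods

## The measurement problem

Screening forage-grass genotypes for waterlogging tolerance conventionally
requires harvesting, drying and weighing shoot biomass, then hand-sorting it
into green and dead (chlorotic/senescent) fractions. `canopypheno`
implements the non-destructive alternative: a single overhead RGB photograph
per plant is segmented into soil, green tissue and dead tissue; the visible
("projected") green and dead canopy areas act as proxies for the harvested
biomass fractions. The tolerance statistic of interest is the waterlogging
tolerance coefficient,

    WTC = 100 x SHB_waterlogged / SHB_control          (percent),

with SHB the shoot biomass in g/plant, and its image-based analogue, the
projected WTC, which replaces SHB by the projected green area (cm²/plant).

## Segmentation pipeline

Each frame is assumed to contain one plant over bare soil, photographed from
above under field illumination. The pipeline is deterministic given the
image bytes and the configuration (which includes a single integer seed).

1. **Background removal.** A per-channel color box is learned from
   hand-labeled soil and plant training pixels (`learn_soil_threshold`).
   The box starts as the envelope of the soil pixels and is tightened
   greedily toward the soil median, one bound at a time, until no plant
   training pixel remains inside or every bound reaches a floor width (2%
   of the channel range per side of the median). Each greedy step picks the
   bound move that excludes the most plant pixels at the least soil cost,
   so soil coverage is maximized subject to excluding plant colors where
   they are separable. The working space defaults to HSV because soil
   separates from foliage chiefly by hue and saturation under varying
   illumination; RGB is available as an option. Hue is circular, so in HSV
   mode the hue axis is rotated to center the soil cluster at 0.5 before
   bounds are fitted (the rotation is stored on the model); without this, a
   reddish-brown soil whose hues straddle the 0/1 wrap point cannot be
   enclosed by one interval.

2. **Color stretch.** Foreground colors are decorrelation-stretched:
   channel covariance is whitened through its eigendecomposition and each
   whitened channel is rescaled linearly to span [0, 255]. This removes
   inter-channel correlation and exaggerates subtle hue differences between
   green and senescing tissue before clustering. When the foreground
   covariance is rank-deficient (e.g., a gray ramp or a two-color image)
   the stretch falls back to a per-channel percentile stretch (defaults:
   anchors at the 2nd and 98th percentiles mapped to 0/255, values
   clipped; a constant channel maps to 128). Background pixels pass through
   untouched, and the fitted parameters are returned for provenance.

3. **K-means clustering.** Lloyd's algorithm with k-means++ initialization
   over the stretched foreground colors, all randomness drawn from one
   `numpy` Generator seeded by the configuration. Points are assigned to
   the nearest centroid by Euclidean distance with ties broken toward the
   lowest centroid index; an empty cluster is re-seeded to the point
   farthest from its assigned centroid; iteration stops when the maximum
   centroid movement drops below the tolerance (default 1e-3) or after
   `max_iter` (default 50) rounds. The within-cluster SSE is recorded after
   every assignment step and is non-increasing by construction. Default
   k = 4, allowing shadowed foliage or residual soil to occupy their own
   cluster before class assignment; k is configurable. On very large
   frames the centroids are fitted on a seeded subsample (cap 200,000
   pixels) but the final assignment always covers every foreground pixel
   exactly.

4. **Class assignment.** Each cluster is mapped to the class of its nearest
   prototype color (green, dead, background), with ties resolved by the
   fixed priority green < dead < background. Because clustering runs in
   the stretched space while prototypes are plain RGB colors, the
   comparison uses each cluster's mean *original* RGB color. Pixels outside
   the foreground mask are forced to background. An optional
   connected-component cleanup (off by default) relabels plant components
   smaller than a minimum size as background.

5. **Quantification.** Pixels are tallied per class (counts always sum to
   H x W) and expressed both as a share of the frame and as a share of the
   plant silhouette; the of-plant denominators are reported as missing, not
   zero, when the frame contains no plant. Counts convert to areas through
   the ground sampling scale: area_mm² = count x (mm per pixel)². The
   scale is a required user input — it cannot be recovered from the image —
   and areas are stored in mm² and reported in cm² (1 cm² = 100 mm²).

## Trial statistics

* **Genotype means** are arithmetic cell means per genotype x treatment; in
  a balanced design these equal least-square means, and the full mixed-model
  machinery is deliberately out of scope. The grand mean is the mean of
  genotype means; CV = 100 x pooled within-genotype SD / grand mean, which
  is undefined (NaN) when no genotype is replicated.
* **Percent change** between treatments is computed from the treatment
  grand means, not as the mean of per-genotype ratios.
* **Pearson correlations** use pairwise deletion of missing pairs, a
  two-sided t-test p-value with n-2 degrees of freedom, and require n >= 3
  and nonzero variance; undefined cells of a correlation matrix become NaN
  with a warning rather than aborting the matrix. Stars default to
  0.05/0.01/0.001 and are configurable.
* **Fisher's protected LSD**: one-way ANOVA first; only if the F-test is
  significant at alpha is LSD = t(1-alpha/2, df_error) x sqrt(2 MSE / n)
  applied (harmonic-mean n under imbalance), with letters assigned by the
  maximal-run sweep over means sorted descending, so two groups share a
  letter exactly when their difference is at most the LSD. A
  non-significant F gives every group one shared letter. Designs with
  fewer than two groups, unreplicated groups, or zero total variance are
  rejected.
* **WTC pairing**: per-genotype WTC divides the genotype's waterlogged mean
  by its control mean (genotype-mean ratio); replicate-wise ratios are not
  the default because replicates are not paired across treatment plots.

## Synthetic data

No field images or replicate-level trait data accompany the bundled trial
summary, so testing rests on two seeded generators.

* **Scenes** (`generate_scene`): Gaussian-textured soil (default RGB
  (110, 85, 65), sigma 5) over which dead ellipses are composited first and
  green ellipses second — green canopy occludes senescing lower leaves, as
  in an overhead view. Default class colors are green (60, 120, 50) and
  dead (160, 140, 60) with per-pixel sigma 5: separable but not trivially
  so. Leaf semi-axes default to 3-12% (green) and 2.5-9% (dead) of the
  frame's short side. The truth mask records the final visible class of
  every pixel and the generator's counts always equal a recount of its own
  mask. What the scenes do *not* emulate: specular water reflections,
  shadows cast across classes, mixed-pixel boundaries at real lens blur,
  and illumination that varies within a class beyond the optional linear
  ramp — so passing recovery tests bound algorithmic error, not field
  error.
* **Cohorts** (`generate_cohort`): 22 genotypes x 6 replicates x 2
  treatments by default, control shoot biomass 700 g/plant with a
  multiplicative genotype effect (SD 0.25) and replicate noise (CV 0.15), a
  50% mean biomass reduction under waterlogging, per-genotype senescence
  sensitivity (uniform on [0.1, 0.6]) splitting biomass into green and dead
  fractions, projected areas linear in the biomass fractions
  (1.2 cm²/g + Gaussian noise), height linear in biomass, and NDVI tracking
  the green fraction. `area_target_r` chooses the area noise SD so the
  planted area-biomass correlation is exact in the population sense, for
  recovery tests. The generating parameters are returned alongside the
  observations.

## Numerical and design choices

* Images are 8-bit sRGB; JPEG is accepted for input but all bit-exact
  fixtures use PNG, because JPEG round-trips are lossy. Masks are written
  as indexed PNG with a fixed palette and reload to identical label arrays.
* Row-major coordinates, origin top-left, 0-based indices.
* Threshold-envelope trimming defaults to the full (0th/100th percentile)
  soil envelope rather than a pre-trimmed one: the tightening step already
  handles plant overlap, and pre-trimming sacrifices soil recall with no
  separability gain. Trim percentiles remain configurable for outlier-heavy
  training sets.
* Missing data are empty CSV cells; zero is never a missingness sentinel.
* Problem sizes in the test suite and the acceptance script — 20 scenes at
  512 x 512, 1,000 calibration simulations at n = 22, 100 recovery cohorts
  of 200 observations — were chosen to make Monte-Carlo error small
  relative to the tolerances being checked while keeping a full run around
  a minute on one CPU.

## Known limitations

* One plant per frame; multi-plant scenes are out of scope.
* The threshold model is a single axis-aligned box (after hue rotation);
  multi-modal soil (wet and dry patches) may need RGB mode or a wider box.
* Cluster-to-class mapping uses fixed prototype colors; strongly atypical
  cultivar colors (e.g., purple-leaved genotypes) require custom prototypes.
* The balanced-design identity between arithmetic and least-square means
  fails for unbalanced user data; the package still reports arithmetic
  means and documents the difference rather than fitting a mixed model.
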