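# Methods

## Scene model for synthetic micrographs

Each simulated field is built clean first, recorded exactly as ground
truth, and degraded last:

1. **Tissue geometry.** A standardized Gaussian random field with
   correlation length ≈ image size / 8 is thresholded at the quantile
   giving the requested `tissue_fraction`, and holes are filled. The blob
   is irregular on purpose — tissue segmentation has to work on
   muscle-section-like outlines, not rectangles. Large-correlation fields
   are drawn on a coarse grid and upsampled; this is equivalent up to
   interpolation and much cheaper. The stored tissue mask is the filled
   mask, so threshold-then-fill segmentation can recover it exactly on
   clean input.
2. **Reporter texture.** Both channels share one multiplicative lognormal
   texture (log-SD 0.15, correlation length 6 px) over the tissue, around
   `mito_green_mean` / `mito_red_mean` (default 8000 of the 16-bit range);
   off-tissue intensity is `background_mean` (default 200). The shared
   texture is what makes the red/green ratio ≈ 1 everywhere outside
   mitolysosomes.
3. **Mitolysosomes.** A homogeneous Poisson point process over the tissue:
   the count is Poisson(*d·A*) with *d* = `puncta_density_per_mm2` and *A*
   the tissue area in mm²; radii are uniform in `puncta_radius_um_range`
   (default 0.3–0.7 µm). Inside each disk GFP is multiplied by
   `quench_factor` (default 0.1) and mCherry by `puncta_red_gain` (default
   1.5). No intensity statistics for real mitolysosomes are published;
   these are configurable placeholders whose *logic* (strong green loss,
   mild red gain) is what matters. Centres are drawn from the tissue mask
   eroded by (max radius + 2 px) so every disk lies strictly inside
   tissue: a quenched punctum is then always an enclosed green-dark hole
   that hole-filling restores to the tissue mask, keeping exact-count
   validation well-posed at the tissue boundary. Overlapping disks are
   allowed and stored individually; the ground truth additionally stores
   the `merged_count` (8-connected components of the union), since no
   detector can separate fused disks. Setting `puncta_min_gap_um > 0`
   rejection-samples pairwise-disjoint disks for exactness tests.
4. **Noise.** Poisson shot noise on the clean scene, then additive
   Gaussian read noise (`noise_sigma`, default 120), then rounding and
   clipping to [0, 65535] — the standard camera model, in that order.

What the generator does **not** emulate: optics (no point-spread function,
no Airyscan), 3D structure, fiber boundaries, autofluorescence, or spatial
inhomogeneity of the point process. Passing tests therefore demonstrate
correctness of the measurement pipeline under the stated model, not
robustness to every real-tissue artifact.

## Detection

Channels are smoothed with a fine filter (default 3×3 median, implemented
as a 19-exchange min/max sorting network, bit-identical to a rank filter
but several times faster). The tissue mask thresholds the green channel
and fills holes; mitolysosomes are green-dark and must not be subtracted
from the tissue area. Candidate pixels must pass **both** thresholds —
`red/(green+ε) > ratio_threshold` (default 2.0, ε = 1 intensity unit) and
`red > red_threshold` — inside the tissue mask; the red bar exists to
reject spurious high-ratio pixels where reporter expression is low.
Components below `min_puncta_area_px` (default 3) are discarded;
connectivity defaults to 8. One ratio threshold and one red-threshold
policy apply to a whole batch, and both are recorded in the output.

**Automatic thresholds are Otsu on log intensities.** Fluorescence classes
are multiplicative (expression × texture), so their spreads are comparable
only on the log scale; linear-scale Otsu can split a broad bright class
instead of isolating the dark background (observed on clean synthetic
fields). The automatic red threshold is likewise computed over the whole
frame — its job is to exclude low-expression *areas*; an Otsu bar computed
within tissue parks itself mid-tissue, above dim puncta.

Membership of a detected component in a restriction mask (e.g. an
immunolabeled cell population) is decided by whether its centroid falls
inside the mask, so puncta straddling a border are attributed exactly once.
Coordinates are 0-based, row-major, pixel-centred; areas are reported in
px and µm².

## Metrics and aggregation

Per image: `count_per_mm2 = N / tissue_area_mm2` and
`occupied_percent = 100 × Σ component area / tissue area`; both are
undefined (an error) on an empty tissue mask. Per-image values are averaged
(unweighted) per animal; the animal is the statistical unit everywhere
downstream, matching how such cohorts are reported (n counts animals, not
images).

## Statistics

Two- and three-way fixed-effects ANOVA use **Type III sums of squares with
sum-to-zero contrasts** (statsmodels OLS + `anova_lm(typ=3)`), the
convention of GraphPad Prism — stated prominently because Type I/II/III
differ on unbalanced data and one genotype group of such designs can have
n = 4 against n = 5 elsewhere. A factor with a single observed level is
dropped with a warning (degenerate three-way designs collapse to the
two-way table). Tukey post-hoc tests compare all cell means of the crossed
factors using the full-model residual mean square (identical to the pooled
within-cell variance, since the full factorial is the cell-means model),
the Tukey–Kramer SE `sqrt(MSw/2·(1/nᵢ+1/nⱼ))` for unequal n, and adjusted
p-values from the studentized-range distribution; at k = 2 this reduces
exactly to the pooled t-test. The tests verify both properties against a
least-squares model-comparison oracle (1e-10) and a numerically integrated
studentized-range CDF (1e-6), and check empirical type-I error ≈ 5% under
a simulated null.

## Cohort design defaults

The simulated cohorts encode the qualitative in-vivo pattern: baseline
densities 2000 / 5000 / 8000 mitolysosomes/mm² for WGC / RCM / SOL
(oxidative muscles have more basal mitophagy), `pink1_ko_multiplier` 0.4,
`polg_multiplier` 1.1, and an interaction multiplier 1/(0.4·1.1) so the
double mutant returns exactly to baseline; between-animal variability is
lognormal (σ = 0.15, median preserved) to keep densities positive. Five
animals per group and 12 images per animal (within the usual 10–15 per
sample). Cohort images default to 256×256 px at 0.2 µm/px — the same
2.6·10⁻³ mm² analyzed area as the single-image default of 512×512 px at
0.1 µm/px, chosen as the package's field size for replicate-cohort
studies; absolute densities were set so a soleus field holds ~20
mitolysosomes.

## Morphometry and densitometry

Region fractions are measured from labeled ROI polygons (the faithful
analogue of dashed-line manual delineation; pixel-centre rasterization,
overlapping polygons rejected) or automatically by a three-class
(background / WGC / RCM) multi-Otsu split of the smoothed log green
channel; fractions are relative to the combined WGC+RCM area, the soleus
excluded. Densitometry models only the normalization arithmetic —
band / whole-lane Ponceau, fold over the reference-group mean — since band
quantification itself happens upstream in image software; background
subtraction is assumed already applied.

## Expression ranking

Tissues with fewer than 20 samples are dropped; quantile normalization
replaces each sample's values with cross-sample means of order statistics,
ties receiving the mean of the tied-rank reference values (deterministic,
permutation-equivariant); tissues are ranked by the mean per-gene rank of
median pathway-gene expression, ties broken alphabetically. The published
QC step that removed samples by expression-distribution criteria is not
specified anywhere; an optional, disabled-by-default filter removes
samples whose median log-expression deviates > 5 MADs from their tissue's
median.

## Numerical and design notes

- Determinism: every generator consumes a single `numpy` Generator seeded
  from its params; identical params ⇒ bit-identical images and tables.
- The noiseless detection contract is exact by construction: threshold in
  the gap between constant background and tissue, holes filled, disjoint
  puncta; the only slack is disk-rasterization area (≈ a pixel's worth per
  punctum) against the analytic ground truth.
- Problem sizes in the tests and acceptance script (20 clean images, 50
  noisy images, 50 replicate cohorts, 2000 null ANOVA replicates, 100
  brute-force grids, 20 ranking seeds) are the package's chosen validation
  conditions; the replicate-cohort run dominates the cost (~8 min on one
  CPU).
- Known limitations: no mixed-effects modeling of image-within-animal
  nesting (animal means only), no machine-learning segmentation, no 3D,
  no fiber-level morphometry, and simulated noise is stationary across
  the field.
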