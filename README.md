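# mitoquant

Quantification of basal mitophagy from *mito*-QC reporter micrographs, with
the surrounding cohort statistics — built as a fully synthetic, ground-truth
validated pipeline.

## The problem

The *mito*-QC reporter is a tandem mCherry-GFP tag on the outer
mitochondrial membrane. Healthy mitochondria fluoresce in both channels;
when a mitochondrion is delivered to a lysosome the acidic environment
quenches GFP but not mCherry, so **mitolysosomes** appear as red-only
puncta. Counting and sizing those puncta per unit tissue area is the
standard readout of basal mitophagy in tissue sections — for example when
asking whether PINK1 loss (a Parkinson's disease gene) reduces mitophagy in
oxidative skeletal muscle, alone or combined with the POLG^D257A^ mutator
allele, in a 2×2 genotype design.

Published work of this kind reports group-mean plots, not raw images, so
this package validates every computational step on simulated micrographs
with known ground truth instead.

## What it implements

- **`mitoquant.synthetic_data`** — seeded simulation of two-channel tissue
  micrographs: an irregular tissue blob, a shared multiplicative
  mitochondrial texture on both reporter channels, red-enhanced /
  green-quenched puncta placed by a homogeneous Poisson point process
  (density *d* per mm², expected count *d·A*), Poisson shot noise followed
  by Gaussian read noise, 16-bit clipping. Also: 2×2 genotype cohorts with
  configurable main/interaction effects on puncta density, two-region
  muscle cross-sections, expression matrices, and blot tables.
- **`mitoquant.image_quant`** — the double-threshold detector: fine (3×3
  median) filter, tissue mask from the green channel (Otsu on log
  intensity, holes filled so green-dark mitolysosomes still count as
  tissue), ratio image `red / (green + ε)`, candidate pixels with
  `ratio > ratio_threshold` **and** `red > red_threshold`, connected
  components, minimum-area filter. Metrics: mitolysosomes per mm² of
  tissue and percent tissue area occupied; per-animal aggregation.
- **`mitoquant.morphometry`** — proportional cross-sectional areas of the
  white gastrocnemius (WGC) vs red/mixed calf muscles (RCM), from labeled
  ROI polygons or automatically from a three-class log-intensity split.
- **`mitoquant.densitometry`** — immunoblot band intensities normalized by
  whole-lane total protein (Ponceau), expressed as fold over a reference
  group.
- **`mitoquant.stats`** — two-/three-way Type III ANOVA (sum-to-zero
  coding, the GraphPad Prism convention) and Tukey–Kramer post-hoc
  comparisons on the studentized-range distribution; the statistical unit
  is the animal.
- **`mitoquant.expression`** — tissue filtering (≥ 20 samples), quantile
  normalization, and ranking of tissues by the median expression of the
  PINK1/PRKN/TBK1/OPTN/SQSTM1 gene set.

## Worked example

The numbered scripts under `analysis/` run the study end to end on
synthetic data; outputs land in `results/` (bulky images in `scratch/`).

```bash
python analysis/02_simulate_cohort.py
python analysis/03_quantify_mitophagy.py
python analysis/04_mitophagy_anova.py
```

prints, for a soleus cohort designed with a 0.4× PINK1-KO effect, a mild
1.1× POLG effect, and a double mutant back at baseline:

```
True group-mean mitolysosome densities (per mm^2):
PINK1  POLG
KO     D257A     8704.0
       WT        3485.0
WT     D257A    10135.0
       WT        9463.0
...
Recovered group-mean mitolysosome densities (per mm^2):
PINK1  POLG
KO     D257A    8552.0
       WT       3454.0
WT     D257A    9309.0
       WT       9149.0
PINK1-KO / WT density ratio (POLG-WT animals): 0.378 (designed 0.4)
...
count_per_mm2: interaction p = 2.29e-03
```

i.e. the image pipeline recovers the designed group structure from pixels
alone, and the factorial ANOVA flags the PINK1 × POLG interaction that
encodes the "double mutant rescued to wild type" pattern.

A `quant` CLI covers batch use on saved TIFFs:

```bash
quant run --manifest scratch/cohort_sol/manifest.csv --out results/quant/
quant single --image scratch/cohort_sol/SOL_WT_WT_1_img01.tif
```

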