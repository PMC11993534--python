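# cardioquant

Quantitative histology of fluorescence-stained cardiac tissue.

Pathological remodeling of the myocardium — cardiomyocyte hypertrophy,
myocardial disarray, changes in chromatin texture and capillary
architecture — is usually assessed qualitatively on stained sections.
`cardioquant` turns multichannel fluorescence micrographs (DAPI nuclei,
WGA membranes/extracellular matrix, isolectin-B4 vessels) into a per-image
table of reproducible, scalar features, so that group comparisons can be
run downstream on numbers instead of impressions.  It is aimed at
cardiovascular histology labs and image-analysis scientists who need
automated, auditable morphometry rather than end-to-end black boxes.

## What it computes

**Nuclear segmentation with region-count low-point selection.**  Each
DAPI image is contrast-equalized (CLAHE), smoothed, and thresholded with a
local-mean adaptive rule.  The threshold sensitivity is chosen per image
by sweeping it and counting segmented regions: noise inflates the count at
permissive settings, over-strict settings fragment nuclei into bright
chromatin islands, and the count minimum in between ("low point") is the
operating point.  No machine-learning model, no training data; every
decision is inspectable in the sweep curve.

**Nuclear morphometry.**  Area, centroid, orientation θ (axial, degrees),
eccentricity `e = sqrt(1 − (b/a)²)` of the inertia-equivalent ellipse, and
staining intensity measured on the raw (pre-equalization) raster.

**Orientation disarray.**  Three complementary statistics over the
per-nucleus orientations θᵢ and the segmented masks:

- orientational order parameter (OOP)
  `f2D = 2(⟨cos²(θ − μ₀)⟩ − ½)`, with μ₀ the axial circular mean — 1 for
  perfect alignment, 0 for isotropy;
- orientation co-occurrence parameter (OCP)
  `OCP = ⟨cos(θₙ − θₙ₊)⟩` over each nucleus and its nearest neighbour in a
  defined direction (default 90°) — stays high when alignment is locally
  coherent but globally scattered, the pattern OOP cannot see;
- a 180-bin rotation histogram of directional edge-pixel counts (mask
  rotated 0°–179° in 1° steps, horizontally differenced, rising edges
  counted), summarized by mean/SD/kurtosis/skewness.

**Masked GLCM texture.**  A gray-level co-occurrence matrix restricted to
in-mask pixel pairs (background never enters), quantized between the
masked intensity extremes, symmetrized and normalized; Haralick contrast,
correlation, energy, homogeneity plus Shannon entropy.  Applied to the
DAPI signal under the nuclear mask and the WGA signal under the matrix
mask.

**Extracellular and vessel architecture.**  WGA network thickness from the
Euclidean distance transform sampled on the medial skeleton; vessel count,
size distribution and centroid spacing; and cardiomyocyte-selective
re-analysis that excludes nuclei whose centroid lies within a proximity
threshold of the nearest vessel pixel (endothelial nuclei sit on vessels,
cardiomyocyte nuclei between them).

**Synthetic phantoms.**  Because feature extractors are only as credible
as their validation, the package ships a seeded phantom generator with
exact ground truth: anti-aliased nuclear ellipses with controllable
orientation models (fixed, uniform, axial von Mises, column-coherent),
chromatin speckle, background noise and illumination gradients, a
Voronoi-border WGA network of prescribed stroke width, and vessel disks.
The whole test suite and the acceptance script run against these phantoms.

## Worked example

```python
from cardioquant import AnalysisConfig, PhantomSpec, analyze_image, generate_phantom

img, truth = generate_phantom(PhantomSpec(seed=21, n_perivascular=8))
row = analyze_image(img, AnalysisConfig(), image_id="demo")
print(f"nuclei: {row['n_nuclei']} (ground truth {truth.n_nuclei})")
print(f"mean nuclear size: {row['mean_nuclear_size']:.0f} px, eccentricity {row['mean_eccentricity']:.3f}")
print(f"OOP (f2D): {row['oop']:.4f}   OCP: {row['ocp']:.4f} ({row['n_ocp_pairs']} pairs)")
print(f"nuclear GLCM contrast: {row['nuclear_contrast']:.3f}, energy {row['nuclear_energy']:.3f}")
print(f"WGA median thickness: {row['wga_median_thickness']:.1f} px")
print(f"vessels: {row['n_vessels']}, median size {row['median_vessel_size']:.0f} px")
```

prints

```
nuclei: 88 (ground truth 88)
mean nuclear size: 318 px, eccentricity 0.820
OOP (f2D): 0.0923   OCP: 0.6274 (88 pairs)
nuclear GLCM contrast: 3.489, energy 0.118
WGA median thickness: 7.2 px
vessels: 5, median size 712 px
```

The phantom holds 80 regular nuclei with uniformly random orientations
plus 8 small peri-vascular ones, and all 88 are found.  OOP near 0.09 is
the isotropy floor for ~90 axial samples (≈ 0.89/√n); OCP near 0.64
matches the analytic baseline ⟨cos Δθ⟩ = 2/π for independent uniform
orientations; the 5 vessel disks of radius 15 px (π·15² ≈ 707 px) are
recovered within 1%.  The cardiomyocyte-selective columns of the same row
exclude exactly the 8 peri-vascular nuclei, raising the selective mean
nuclear size to 338 px.

## Command line

```bash
cardioquant phantom --out fixtures/ --seed 1 --count 5   # phantom TIFFs + truth JSON
cardioquant analyze fixtures/ --out results/             # batch feature table (CSV)
cardioquant validate --phantom-dir fixtures/             # count-concordance report
```

Every run writes its effective configuration (`config.yaml`) and a
manifest with per-image status next to the feature table; identical
inputs and configuration produce byte-identical CSVs.

## Layout

```
src/cardioquant/
  image_io.py      TIFF loading, channel mapping, CLAHE, Gaussian smoothing
  segmentation.py  adaptive threshold, low-point sweep, nuclei/matrix/vessel masks
  morphometry.py   per-nucleus features and per-image summaries
  orientation.py   orientation histogram, OOP, OCP, rotation histogram
  texture.py       masked GLCM, Haralick descriptors, WGA thickness
  vessels.py       vessel metrics, cardiomyocyte-selective analysis
  phantom.py       ground-truth phantom generator, count validation
  config.py        serializable run configuration
  pipeline.py      per-image orchestration, batch CSV + manifest
  cli.py           `cardioquant` command-line interface
```

See `docs/methods.md` for the underlying models, parameter defaults, and
known limitations.
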