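# Methods

This note documents the models and procedures implemented in
`cardioquant`, the defaults and why they were chosen, what the synthetic
phantoms do and do not emulate, and the numerical conventions a user
needs to interpret the outputs.

## Image model and preprocessing

Inputs are registered single-channel rasters for up to three stain roles
(DAPI → `nuclear`, WGA → `matrix`, isolectin B4 → `vessel`), loaded from
8- or 16-bit TIFFs and normalized to `[0, 1]` by the bit-depth maximum.
Channel assignment is configuration with the conventional RGB default
(blue = nuclear, red = matrix, green = vessel); single-channel files per
role are equally supported.  All outputs are in pixels / arbitrary units;
physical conversion is possible only when `pixel_size` metadata is
supplied and is never implied.

Preprocessing for segmentation is CLAHE (clip limit 0.01, 8×8 tile grid)
followed by Gaussian smoothing (σ = 1.5 px).  These defaults are
engineering choices, not reproductions of any published setting: the clip
limit is conservative enough not to amplify empty-background noise into
structure, and σ = 1.5 suppresses shot noise without bridging adjacent
nuclei at typical 40× sampling.  Intensity and texture statistics are
always computed on the **raw** raster — CLAHE is a segmentation aid and
would otherwise contaminate cross-sample intensity comparisons.

## Segmentation

All channels use a local-mean adaptive threshold: pixel `p` is foreground
iff `I(p) > m_w(p) · (1 + s)`, with `m_w` the mean over a `w×w` window
(default: 1/8 of the smaller image side, forced odd) and `s` a
sensitivity offset.  The threshold is floored at 1e-9 so that
floating-point residue in the filtered mean cannot promote exactly-zero
background.  Objects are 8-connected; 8-connectivity tolerates the 1-px
diagonal necks rasterized ellipses produce.

For nuclei, `s` is selected per image by sweeping 21 values over
`[0, 0.5]` and counting regions (after an area filter, default
min_area = 50 px).  The count curve is U-shaped in realistic conditions:
noise creates spurious regions at permissive `s`, fragmentation of nuclei
into bright-chromatin islands inflates the count at strict `s`, and the
true count sits at the minimum in between.  The curve is smoothed with a
moving median of width 3 (single-point noise minima must not win) and the
**lowest** sensitivity attaining the global minimum is selected —
tie-breaking toward the permissive side avoids splitting nuclei into
euchromatin and heterochromatin fragments.  Sensitivities yielding an
empty segmentation are excluded from the minimum search; an empty image
raises instead of silently reporting zero.  The strict-side limb of the U
only materializes when the local mean is commensurate with nuclear
intensity, i.e. when the window is not much larger than a nucleus; with
the default 1/8-image window on sparse fields the curve is
monotone-then-flat, which selects the same plateau.

Border-touching nuclei are excluded by default (partial nuclei bias area
and eccentricity); `keep_border` restores them.  There is deliberately no
watershed post-splitting: overlapping nuclei count once, a documented
limitation chosen for robustness to noisy or disrupted nuclear borders.

The WGA matrix mask uses a fixed sensitivity (default 0.05) with no area
filter, since the membrane network spans the image as one structure.
Vessels use a **global Otsu threshold** instead of the local-mean rule:
vessel channels are sparse bright blobs on a dark field, the histogram is
bimodal, and Otsu lands halfway up the edge ramp — on the geometric
outline — recovering disk areas within ~1%, where the local-mean rule
systematically dilated them by ~10%.  Lumina are filled before labeling
so annular cross-sections count once with their full area.

## Morphometry conventions

Per-nucleus features come from the second central moments of the pixel
set (inertia-equivalent ellipse).  Orientation θ is the major-axis angle
against the image horizontal, counterclockwise positive in a y-up frame,
wrapped to (−90°, +90°]; it is axial (θ ≡ θ + 180°).  Eccentricity is the
standard `sqrt(1 − (b/a)²)` — 0 for a circle — which is the only
definition consistent with region-properties conventions and with "0
means circular".  Summary SDs use the population (n) denominator; the
per-image intensity summary is the median of per-nucleus median
intensities, reported on the loaded `[0, 1]` scale.

## Orientation statistics

Orientation-histogram statistics (mean, SD, kurtosis, skewness) are
computed on the raw orientation values, not on binned counts; kurtosis is
non-excess (normal → 3) and both use the biased moment estimators.  Note
the arithmetic mean/SD of axial angles are frame-dependent descriptive
statistics — meaningful for comparing images under a shared convention,
not rotation-invariant quantities.

**OOP.**  `f2D = 2(⟨cos²(θ − μ₀)⟩ − ½)` with μ₀ the axial circular mean,
i.e. half the argument of the mean doubled-angle unit vector.  An
arithmetic μ₀ would be wrong for axial data (the mean of {+89°, −89°} is
90°, not 0°); with the axial mean, f2D equals the resultant length of the
doubled-angle vectors, is confined to [0, 1], and is invariant to a
global rotation of all orientations.  For n isotropic samples the
expected value is ≈ 0.89/√n, not 0 — per-image OOPs from ~80 nuclei have
a floor near 0.1, which is why the isotropy check in the acceptance
script uses a 600-nucleus phantom.

**OCP.**  For each nucleus, the neighbour is the nearest other nucleus
within `max_distance` (default 150 px) whose displacement lies within a
±45° cone about the defined direction (default 90°, applied axially so
"above" and "below" both qualify).  The pair contributes `cos Δθ` with Δθ
the axial orientation difference wrapped to [−90°, 90°] — without the
axial wrap, two identically oriented nuclei could score −1.  OCP is the
mean over nuclei with a valid neighbour, and the number of contributing
pairs is always reported.  Under independent uniform orientations the
expectation is `⟨cos Δθ⟩ = 2/π ≈ 0.64`, so OCP values must be read
against that baseline, not against 0.  The neighbour rule (cone, radius,
direction) is configuration and logged, since "neighbour in a defined
direction" admits several formalizations.

**Rotation histogram.**  The mask is rotated 0°–179° in 1° steps about
the image centre, and for each direction the strictly positive horizontal
first differences (background→foreground transitions) are counted, so
each border is counted once per scan line.  Rotation uses bilinear
interpolation with a light Gaussian regularization (σ = 0.8) before
re-binarizing at 0.5: with nearest-neighbour rotation, repeated
rasterization leaves single-pixel jags on near-axis-aligned boundaries
that a scan row crosses several times, inflating individual bins by tens
of percent; the regularized rotation keeps the profile equivariant under
pre-rotation to within ~5% per bin and a centred disk isotropic to ~1%
CV.  The summary `rotation_stat` is the mean count over the 180
directions — it scales with total boundary length, so more (or smaller,
for fixed area) objects raise it.

## Texture

The GLCM is computed over in-mask pixel pairs only: both endpoints must
lie inside the mask, which keeps object-border background pairs — pure
segmentation artifacts — out of the matrix.  Intensities are quantized
into `n_levels = 8` equal bins between the masked minimum and maximum
(mirroring the default behaviour of the common region-texture tools);
offsets default to distance 1 at 0°, 45°, 90°, 135°, accumulated into a
single orientation-agnostic matrix, then symmetrized and normalized.
Descriptors use 0-based level indices: contrast `Σp(i−j)²`, homogeneity
`Σp/(1+|i−j|)`, energy `Σp²`, entropy `−Σp log₂ p` (bits), correlation
`Σp(i−μᵢ)(j−μⱼ)/(σᵢσⱼ)` reported as `None` (undefined) when a marginal is
degenerate — a constant region has no correlation, and `NaN` would
silently poison downstream statistics.  Both energy and entropy are
reported, as the two are often conflated in texture nomenclature.
Because quantization is min–max relative, descriptors are invariant to
additive shifts and to modest brightness rescaling; note this also means
that when the mask includes dim anti-aliased boundary pixels, the
intensity range is boundary-dominated and interior-amplitude differences
compress — texture comparisons are most sensitive when masks are tight.

WGA thickness: Euclidean distance transform inside the mask, sampled at
medial-skeleton pixels only (off-axis distances under-estimate local
width), with local width `2d − 1` at a skeleton pixel of distance `d`
(the medial pixel plus `d − 1` to each side; exact for odd pixel widths,
±1 px for even).  Mean, median, and max are reported.

## Vessels and selective analysis

Vessel metrics are per-object areas (count, median/mean/SD/relative SD)
and centroid nearest-neighbour distances; an empty vessel map is a valid
avascular field, reported as zero count rather than an error.
Cardiomyocyte selection evaluates the distance transform of the
vessel-free region at each nucleus **centroid** (threshold default 15 px
at 40×): footprint-based tests would discard large cardiomyocyte nuclei
that merely graze a vessel.  The selection is monotone in the threshold,
the audit (per-nucleus distance, kept/excluded) is exported, and an empty
vessel mask keeps all nuclei with a logged warning.  Selective summaries
re-run morphometry, masked nuclear texture, and orientation statistics on
the kept subset and are flagged as such in the feature table.

## Phantoms: what they emulate, and what they do not

The generator renders anti-aliased ellipses (semi-major ~N(12, 1.5²) px,
axis ratio 2, rejection-sampled to non-overlap) with chromatin speckle
(smoothed Gaussian noise, correlation length ~3 px, amplitude 0.12),
background level 0.06, additive Gaussian noise (SD 0.02), and a linear
illumination gradient (amplitude 0.10 across the width) — the defaults
are one fixed set of "moderate difficulty" conditions.  The WGA channel
is the Voronoi-boundary band of the nucleus centroids at a prescribed
stroke width (the band `d₂ − d₁ ≤ w` of the two nearest-centroid
distances has geometric width exactly `w`), so membranes and nuclei are
geometrically consistent as in tissue.  Vessels are anti-aliased disks;
optional small peri-vascular nuclei at a fixed gap from the vessel edge
emulate endothelial nuclei for testing selective analysis.  Orientation
models: fixed, uniform, axial von Mises (doubled-angle sampling), and
column-coherent (columns share an orientation; column orientations are
evenly spaced over the axial circle and shuffled, so the global OOP
vanishes by construction while within-column co-occurrence is perfect —
the discriminating scenario for OCP).

Phantoms deliberately do **not** model optics (PSF, photobleaching,
chromatic shifts), real chromatin substructure, overlapping or touching
nuclei (unless opted in), fibrosis, or staining variability.  Passing the
phantom suite therefore demonstrates that the *measurement chain* is
correct on known geometry under noise and illumination confounds — it
does not certify segmentation accuracy on arbitrary tissue, where
focus, section thickness and stain quality dominate.

Problem sizes used in tests and the acceptance script — 512×512 fields
with 40–100 nuclei (20 phantoms for the concordance run), one 800×800
column-coherent field, one 1600×1600 isotropy field — are the package's
chosen validation scale; all generation is seeded and bit-reproducible.

## Numerical choices and degenerate inputs

- Empty masks, empty label maps, single-nucleus orientation requests, and
  constant count vectors raise typed errors (or return `None` sentinels
  where a value is documented as undefined) instead of propagating NaN.
- The sweep's region-count minimum excludes empty segmentations; ties
  break toward the lowest sensitivity.
- f2D is clamped to [0, 1] against 1e-16-scale arithmetic residue.
- Pearson r between count vectors is `None` when either vector is
  constant.
- The batch pipeline isolates failures per feature group per image: a
  missing or degenerate channel nulls that group's columns with a reason
  string, and only a run in which every image fails exits nonzero.

## Known limitations

- No watershed: merged nuclei under-count; the sweep's low point partially
  compensates by preferring thresholds that separate nuclei.
- The rotation histogram is O(180 × image) and dominates per-image
  runtime on large fields.
- OCP depends on three neighbour-rule knobs; cross-study comparisons must
  hold them fixed.
- GLCM descriptors are not comparable across different `n_levels` or
  offset sets, and published absolute values from other tools are not
  bit-reproducible without their exact quantization settings.
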