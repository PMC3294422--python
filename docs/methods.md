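# Methods

## The segmentation model

The pipeline assumes microglia labeled throughout their cytoplasm (e.g.
cytosolic EGFP), imaged as a 2D projection of a thin (~10 µm) slab so that
one cell appears once, with a soma markedly brighter than its processes
and a background that varies smoothly across the field.  It makes one
biological prior explicit: the expected 2D footprint of a single cell,
the target cell size (TCS).  Segmentation is then a root-finding problem
per cell — find the local threshold at which the connected component
around the cell's position has the prior's area — rather than a global
intensity decision, which is what makes the result insensitive to
illumination inhomogeneity, staining strength, and pixel saturation.

### Projections

Stacks project to 2D by per-pixel maximum (default) or mean over slabs of
10 µm starting at depth 0 and repeating every `slab + gap` µm (gap
default 20 µm, so no plane — and in practice no cell, soma diameter being
~10 µm — contributes to two projections).  A trailing slab with less than
half its nominal thickness of data is dropped; a stack thinner than one
slab yields an empty list with a warning.  The section naming of such
projections is ambiguous in the field ("MIP" is used for both maximum and
mean); both are implemented and the choice is an explicit, logged
parameter defaulting to maximum.

### Detection

Global thresholds fail under illumination gradients, so detection works
on local contrast: the image (lightly smoothed by a (2r+1)² uniform
filter, r = 1 px) divided by a coarse background estimate (uniform filter
over an 80 µm window — much larger than a cell, much smaller than the
illumination scale).  On this ratio image the background sits near 1
everywhere.  All regional maxima (8-connectivity) are collected; since
noise maxima vastly outnumber cell maxima, the detection level is a
robust outlier rule on the peak heights, median + 3·MAD.  On a dark
background where the only maxima are real objects, MAD = 0 and the level
degenerates to the objects' plateau value, which is the desired behavior.
Objects are 8-connected components of the *unsmoothed* contrast at that
level (smoothing erodes the rim of small plateaus, which matters against
the area filter); components with area ≤ 50 µm² are discarded and each
survivor's unweighted centroid is a candidate cell position.  Candidates
closer than 5 µm merge, keeping the larger seed object.  Detection is
exactly invariant to multiplying the image by a positive constant.

### Threshold iteration

Within the 120 µm local region, starting from the 256-bin Otsu threshold,
each iteration k measures the area A_k (µm²) of the suprathreshold
8-connected component containing the CP (if the CP pixel is below
threshold, the nearest component within 10 µm; possibly empty).  If
|A_k − TCS| ≤ tol the mask is accepted as converged.  Otherwise

    T_{k+1} = clamp( T_k + g · ē_k · (patch_max − patch_min) ),
    ē_k = (1/k) Σ_{i≤k} (A_i − TCS) / max(A_i, TCS),

with gain g = 0.05 and the clamp keeping T inside the open patch range.
Two deliberate numerical choices:

- **Bounded per-iteration error.**  The relative error is normalized by
  max(A_i, TCS), bounding it in (−1, 1).  A worst-case low start (half
  the Otsu value sits inside the noise floor) yields a component spanning
  most of the LR; an unbounded error (A/TCS ≈ 30) would dominate the
  running mean for dozens of iterations and pin the threshold at the
  patch maximum.  With the bounded form the update is a damped step of at
  most g·range per iteration in either direction.
- **Stagnation requires a settled threshold.**  The iteration stops
  unconverged when the last 3 areas are identical (exact pixel count)
  *and* the threshold has stopped moving (|ΔT| ≤ 1e−9 · range).  Area
  alone is not a fixed point: while the threshold traverses a gap in the
  intensity histogram (e.g. between process and soma intensities) the
  area is constant for several iterations although the iteration is still
  travelling.  On a two-valued patch the threshold walks to the clamp and
  then both quantities are fixed, so quantized inputs still terminate
  early.  A hard cap of 100 iterations guarantees termination.

Cells whose iteration ends outside TCS ± tol are reported with status
`not_converged_discard` and excluded from morphometry — the conservative
reading of "accurate mask".  The iteration is scale-equivariant: scaling
intensities by c > 0 scales the Otsu start, the range, and every
threshold, leaving all masks bit-identical.

### Soma extraction and validation

Soma pixels are those inside the cell mask exceeding T_final · (1 + x),
x = 0.5 by default; 8-connected components ≥ 16.7 µm² are soma masks.
The threshold-relative reading (rather than "50% above the mean of the
rest of the mask") is used because the soma increment is naturally swept
against the final threshold; the alternative reading changes only the
operating point, and soma size is monotone non-increasing in x either
way.  Validation: masks touching the outermost pixel ring of the (possibly
edge-clipped) LR are `border_touch`; zero somata → `no_soma` (cell body
above/below the slab); two or more → `multi_soma` (dividing cell or
unresolved pair).  Accepted cells whose mask centroids fall within 5 µm
of a larger-seeded accepted cell are demoted as duplicates.

### Morphometry

- Perimeter: Crofton formula with 4 directions.  On a rasterized disk of
  radius 30 px it is within 1% of 2πr, where naive 8-connected boundary
  counting overestimates by ~27%; a single isolated pixel has the weight
  (1 + 1/√2)·π/2 ≈ 2.68 pixel units.
- Spread: mean Euclidean distance from the unweighted mask centroid to
  the eight extremal boundary points (top-left-most, top-right-most, …).
  The centroid is taken from the mask, not the intensities.
- Eccentricity: the moment-ellipse definition (√(1 − (b/a)²)); the
  "smallest enclosing circle" phrasing sometimes used for this quantity
  is inconsistent with typical reported medians (~0.79), which only the
  moment definition produces.
- Roundness: 4π·A/P² with both in physical units; pixel size cancels.
- Soma size: area of the unique accepted soma mask.

### Expression and statistics

Per-cell marker expression is mean intensity over the cell mask divided
by mean intensity over the LR minus the mask.  The quotient (not
subtraction) makes the value invariant to multiplicative staining and
illumination variation.  Note that in crowded fields the LR background
contains neighboring cells, which inflates the denominator slightly — an
intrinsic property of the estimator, visible in the synthetic slope-
recovery test.  Per-cell values aggregate to per-animal means before any
group statistic; normalization expresses each animal as percent of the
control group's grand mean; significance uses the classical
pooled-variance two-sample t-test (Welch optional); correlations are
squared Pearson coefficients, averaged per animal for group reporting.

## The synthetic generator

The generator renders the features the method must survive, with full
ground truth (the pre-noise support — evaluation measures segmentation,
not denoising):

- **Shape regimes.**  Resting: soma radius 2.5–3.5 µm, 6–8 random-walk
  processes (3 px wide) grown round-robin until the footprint reaches an
  area target drawn from U(460, 540) µm², path length capped at 40 µm.
  Activated: soma radius 4.5–6 µm (plateau > 65 µm²), an elliptical body
  sized to the area target, 0–2 short stubs.  Both regimes target the
  ~500 µm² prior so that in-regime cells *can* converge; the radial
  extent of any cell is capped at 19 µm (enforced pixel-wise), so the
  default 40 µm center separation guarantees disjoint supports.
- **Intensities** (8-bit scale): autofluorescence background 30, Gaussian
  noise σ = 5, process/body at +30 over background with ±2 per-pixel
  texture, soma plateau at the 8-bit ceiling (rendered +225 and clipped —
  saturated somata are the norm in real acquisitions and the pipeline is
  expected to tolerate them).  Dim processes a few noise-σ above
  background reproduce the regime in which local Otsu starts land just
  above the process band and the iteration walks down to capture the
  footprint; the soma criterion 1.5·T_final then falls between process
  and soma intensities.  These values were fixed once, as the package's
  imaging model, before the validation statistics were frozen.
- **Field effects.**  A left-to-right linear illumination gradient of
  amplitude 0.3 multiplies signal, background and noise alike (shot-like
  noise), so each local region is an intensity-scaled copy of the same
  model.  The marker channel adds each cell's footprint at
  level·(1 + gain·activation) over a constant background, sharing the
  illumination field, so quotient ratios are gradient-invariant.
- **Reproducibility.**  Every stochastic step flows from one
  `numpy.random.Generator` seed; identical seeds give bit-identical
  fields.

What the generator does **not** emulate: the point-spread function (edges
are sharp, not blurred), depth-dependent attenuation, vascular shadows,
autofluorescent debris, cell-intrinsic intensity gradients along
processes, and motion.  Passing validation therefore demonstrates the
pipeline's logic — convergence, locality, scale-invariance, validation
tests, metric correctness — not photometric realism; on real data the
area accuracy will be bounded by focus and labeling quality rather than
by the iteration.

## Validation statistics and problem sizes

`scripts/acceptance.py` recomputes three statistics from scratch; the
suite asserts the same properties at the same sizes.

- **Start-threshold robustness**: 11 fields × 20 cells (220 accepted
  cells); every accepted cell re-segmented from Otsu/2 and Otsu×2; the
  statistic is the mean of |A₁ − A₂| / mean(A₁, A₂) × 100.  Typical
  values ~5–6%.
- **Detection rate**: five 20-cell fields (300 µm, separation 40 µm,
  mix 0.5); greedy nearest-first one-to-one matching of accepted masks to
  truth within 10 µm; pooled over fields.  Typically 95–100%.
- **Area accuracy**: same fields; 100 − mean |A_auto − A_truth|/A_truth
  × 100 over matched cells.  Typically ~95%.

These sizes keep a full validation run under a minute on one CPU while
leaving the statistics stable to ±1–2% across master seeds.

## Known limitations

- 2D only; touching cells are rejected (border/multi-soma), not split —
  dense or aggregated tissue lowers the detection rate by design.  Faint
  touches at dim process tips can be legitimately resolved by the
  threshold iteration, so "touching" in the ground truth is not a
  guarantee of rejection.
- One TCS per run: fields mixing strongly different cell footprints
  (e.g. different brain regions) need separate runs with recalibrated
  priors.
- The soma criterion presumes soma pixels ≳ 1.5× the final threshold;
  labeling chemistries without a bright cell body (e.g. membrane-only
  labels) break the soma test and with it the validation step.
- Masks inherit threshold noise: single-pixel holes and ragged borders
  are not cleaned up, so absolute perimeter and roundness values are
  estimator- and noise-dependent; comparisons are meaningful within a
  pipeline configuration, not across tools.
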