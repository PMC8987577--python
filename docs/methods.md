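# Methods

This note documents the models, conventions and numerical choices behind
`gliaquant`, and what the synthetic fixtures do and do not establish.

## Pipeline model

Each animal contributes one 3-channel confocal z-stack of the larval
ventral nerve cord, analyzed strictly plane by plane (no volumetric
reconstruction). Per plane and channel:

1. **Denoise** by unsharp masking:
   `out = img + amount · (img − G_σ(img))`, where `G_σ` is a Gaussian blur
   with standard deviation `radius` pixels, and the output is clipped to
   the input range. Defaults: amount 2, radius 20 for the astrocyte and
   cortex-glia channels; amount 3, radius 20 for the nuclei channel.
2. **Binarize** with a global threshold chosen by a per-channel decision
   tree (below). Foreground is strictly above the scalar threshold.
3. **Segment the cortex** from the union of the cortex-glia and nuclei
   masks: dilation fill → hole fill → erosion (below).
4. **Score**: AMI = 100 · (cortex-glia perimeter) / (cortex area);
   AIS = 100 · (astrocyte∩cortex pixels after cell-body exclusion) /
   (cortex area). Zero-area cortex leaves both scores missing (NaN), not
   zero.

### Threshold decision tree

Otsu is computed first and inspected once (single pass — the fallback
result is not re-inspected):

| channel     | blown out → | else blacked out → | else |
|-------------|-------------|--------------------|------|
| nuclei      | Triangle    | Li                 | Otsu |
| cortex glia | Triangle    | —                  | Otsu |
| astrocyte   | Triangle    | Yen                | Otsu |

*Blown out*: removing foreground components under 75 px (8-connected) and
comparing the middle third of image rows — the band occupied by the
neuropil in longitudinal sections — before and after must reduce white
pixels by ≥ 7% (non-strict, matching the stated rule). The band axis is
configurable for other sectioning geometries. *Blacked out*: total white
fraction strictly below 2%. Blown-out is checked before blacked-out; both
diagnostics are logged per plane regardless of the branch taken. A
constant image cannot be thresholded and returns an all-background mask
attributed to Otsu with a warning.

The 3/2/1 per-image ranking utility used to shortlist global algorithms
is exposed (`score_algorithm_rankings`) for users who want to audition
additional algorithms on their own data; the decision tree itself is
restricted to the four named algorithms.

### Cortex segmentation

- **Dilation fill** (`n` = 15 px, `thresh` = 0.10): one simultaneous
  pass; a background pixel flips to foreground iff the fraction of
  foreground among its in-image neighbors within a Euclidean disk of
  radius `n` (center excluded, no padding) is strictly greater than
  `thresh`. Implemented by FFT convolution with integer rounding, so
  counts are exact.
- **Hole fill** (`hole_size` = 5000): background components (8-connected,
  configurable) smaller than `hole_size` pixels that do not touch the
  image border are filled. The threshold is an area in pixels.
- **Erosion** (`erosions` = 10): each pass removes foreground pixels with
  any background among their 8 neighbors; the image border counts as
  background.

The four defaults are the grid-search optimum reported for this
parameterization; `parameter_grid_search` re-ranks any grid against
manual masks by mean OL/M, tie-broken by mean OL/A, and also flags the
Pareto front on the two means, since the bi-objective "best of both" has
no canonical scalarization.

### Scoring conventions

- The perimeter estimator counts exposed unit edges (edges facing
  background or the border). It is exactly verifiable by enumeration, and
  AMI is used comparatively (against ordinal manual scores), where
  consistency matters more than Euclidean calibration. A different
  estimator can be injected via `perimeter_func`.
- AMI measures the full plane's cortex-glia mask by default while
  normalizing by cortex area; `clip_ami_to_cortex` restricts the
  perimeter to the cortex region.
- Roundness (`4πA/P²`) uses the same perimeter estimator; a large digital
  disk scores ≈ π²/16 ≈ 0.62 under it, which is why the default
  cell-body roundness cutoff is 0.5 rather than a value near 1.
- Cell-body exclusion operates on the cortex-clipped astrocyte mask.
  Objects with area in [50, 800] px, extent ≥ 0.6 and roundness ≥ 0.5 are
  removed. These cutoffs are calibrated to the synthetic-fixture scale
  (bodies are disks of radius 5–7 px); on real data they must be
  recalibrated to the magnification.

### Spatial statistics

- Global scores are unweighted means over a stack's planes, excluding
  missing planes.
- The sliding window has width 10 (percent of normalized depth) and step
  1 by default; windows are `[c − w/2, c + w/2)` clipped to [0, 100],
  taken closed on the right wherever the window reaches the dorsal
  surface so the dorsal-most planes are not orphaned. Per-animal means
  come first, then group mean ± SEM across animals (SEM with ddof 1;
  undefined for a single animal). Windowed AMI–AIS correlations pool all
  groups and require at least 3 animals; the plotting helper shades
  windows with p < 0.001.
- Spearman's ρ is the Pearson correlation of mid-ranks. For n ≤ 8 the
  two-sided p-value is computed by exhaustive permutation; otherwise by
  the t approximation.
- Kruskal–Wallis uses the tie-corrected H with a χ² reference; Dunn
  pairwise z statistics use pooled mid-ranks with the tie-corrected
  variance. Raw and Holm-adjusted p-values are both reported because no
  single adjustment is canonical for this design.
- The validation regression is OLS of automated on manual scores with a
  t-based 95% CI on the slope; pairs with |manual − automated| > 6 score
  units are flagged and the fit is repeated without them.
- ICC(3,k) is the two-way mixed, consistency, average-of-k-raters
  intraclass correlation, `(MS_targets − MS_error)/MS_targets` from the
  two-way ANOVA without interaction.

## Synthetic fixtures

The generator emulates a longitudinal section: a central neuropil band
(the middle third of rows, so the blown-out detector's band convention is
exercised honestly) flanked by cortex bands with rounded corners (tissue
has no 90° corners; sharp fixture corners would interact artificially
with the Chebyshev-metric erosion) and an empty 20-px margin. Nuclei are
densely packed disks (radius 5–8 px, clipped at the cortex surface, ≈ 60%
area coverage) reflecting the near-solid soma packing of the real cortex;
this density is what lets the dilation fill close all nucleus–membrane
gaps at the default parameters. Cortex glia interpolate from a 2-px
Voronoi-boundary mesh over the nuclei plus a 3-px surface sheath
(globularity 0) to a fixed set of stereotyped disks (globularity 1) by
removing a matching fraction of mesh segments and adding disks, so the
ground-truth perimeter is strictly decreasing in globularity. Astrocytes
have cell bodies nudged just inside the interface, arborizations rooted
at those bodies (large connected components, as in real tissue — this
matters because free-floating speckle would trigger the blown-out
branch), and cortex-penetrating processes grown pixel by pixel until the
planted infiltration pixel target is met exactly.

Rendering: background level drawn once per image from 20 ± 10, object
levels from 180 ± 20, Gaussian blur σ = 0.8 px (a realistic confocal PSF
at ~150 nm pixels), additive Gaussian noise σ = 4, clipped to [0, 255].
"Noiseless" conditions set blur and noise to 0, making binarization exact
and ground-truth recovery checkable to the pixel.

What the fixtures do **not** model: depth-dependent attenuation, an
anisotropic PSF, autofluorescence, staining variability across animals,
or genuinely ambiguous cortex boundaries. Passing the recovery tests
therefore shows the machinery is correct under its stated geometry, not
that real stacks will reach the same overlap numbers; the real-data
validation path (manual masks and scores through `validate_run`) exists
for that purpose.

A measured property of the default rendering worth knowing: the ~1-px
blur halo around thin processes biases AIS upward by roughly 10% relative
at infiltration fractions of a few percent. This mirrors the behavior of
threshold-based overlap scoring on real images (automated infiltration
scores tend to run above manual ones) and is why noisy-recovery checks
are stated on the mean relative error.

## Problem sizes

Test and acceptance runs use 256×256 fixture planes (the geometry above),
20-seed recovery batches, 100–200-seed statistical calibrations, and a
3-group × 3-animal manifest at 144×192–192×224 for end-to-end runs —
sizes chosen so the full suite exercises every path in well under an
hour on a laptop while keeping every statistical margin (e.g., the null
|ρ| calibration at 30 animals) meaningful.

## Known limitations

- Strictly 2D: fine processes crossing between imaging planes are
  invisible, which underestimates territory and infiltration.
- The decision tree can flag legitimately sparse globular planes as
  blown out when the band contains only a handful of bright pixels
  (reduction is a ratio); the per-plane decision log exists to audit
  exactly this.
- Cell-body exclusion cutoffs are scale-dependent and must be retuned
  per magnification.
- The identity of global thresholding algorithms beyond the four named
  ones is out of scope; the ranking utility supports auditioning more.
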