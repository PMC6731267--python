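# Methods

## Scope and model

`ringtrack` classifies the spatial distribution of γH2AX
immunofluorescence in interphase nuclei imaged at 20× widefield scale.
The unit of analysis is the nucleus; the output per nucleus is one of
three mutually exclusive phenotypes (FOCI, RING, UNIFORM) plus the
supporting measurements, and the population readout is the proportion
of each phenotype per field and condition. The pipeline is rule-based
and fully deterministic: no training, no randomness outside the phantom
generator.

## Segmentation

Nuclei are detected on the DAPI channel only:

1. Gaussian smoothing, σ = 2 px (reflective padding; mass-conserving).
2. Global binarisation at the threshold maximising between-class
   variance over a 256-bin histogram (Otsu). Foreground is strictly
   above the threshold. Because the histogram spans the image's own
   range, the foreground set is invariant under positive intensity
   rescaling. The threshold is written to the provenance log. The
   variance curve can tie exactly across an empty histogram gap; any
   co-maximiser yields the same segmentation up to pixels lying inside
   the gap, which is empty by definition.
3. Morphological refinement: `n_dilations` (default 2) with a disc of
   radius 3 px, hole filling, then `n_erosions` (default 2) with the
   same disc. Erosion treats the image border as foreground so
   border-touching objects do not erode from the edge.
4. 8-connected component labelling, labels assigned in raster-scan
   order of each component's first pixel.

Candidate objects then pass four filters, all with strict inequalities,
in the fixed order area → eccentricity → regularity → intensity (the
first failure is recorded as the rejection reason):

* area > 400 px² — removes debris and fragments;
* eccentricity of the moment-matched ellipse < 0.8 — removes elongated
  junk and dividing cells;
* circularity 4πA/P² > 0.85 — removes irregular clumps (P is the
  standard digital contour-length estimator; a one-pixel object has
  P = 0 and is assigned infinite circularity, which is irrelevant in
  practice because the area filter fires first);
* mean DAPI intensity < 2 × the median of the mean intensities of
  **all** candidates in the field — removes saturated/mitotic objects.
  The median is computed once, before any rejection, so the accepted
  set does not depend on candidate order.

Objects touching the field border are kept by default;
`exclude_border` drops them before the filters (and before the median)
for users who prefer unbiased geometry at the cost of nuclei counted.

## Phenotype rules

**Foci.** Within each accepted nucleus, γH2AX is binarised adaptively:
a pixel is foreground iff its intensity strictly exceeds
(1 + α) × the mean intensity of nucleus pixels inside a w × w window
centred on it. Pixels outside the nucleus never enter the window
statistics, so the rule sees only the nucleus's own background. The
defaults w = 15 px, α = 0.15 suit foci of a few pixels' width (σ ≈ 2 px
at 20×): the window is large enough that a focus does not dominate its
own local mean, and the multiplicative offset keeps the rule exactly
scale-invariant. Foci are 8-connected foreground components of at least
4 px (a guard against single-pixel noise). The nucleus is FOCI iff
count/area > 0.0035 px⁻², strictly: a density of exactly 0.0035 is not
FOCI. The cutoff is pixel-size dependent and is exposed as a parameter
for other magnifications.

**Ring.** For non-foci nuclei, one intensity profile is cast from the
nuclear centre of mass to each boundary pixel (members 8-adjacent to a
non-member), sampled at steps of at most 1 px with bilinear
interpolation, endpoints included. If a concave nucleus's centroid
falls outside it, the nearest member pixel is used as the ray origin
(logged). All rays are linearly resampled to the length L of the
longest ray and averaged pointwise. The averaged profile is split at
index ⌊0.75·L⌋; the nucleus is RING iff mean(last quartile) −
mean(first three quartiles) strictly exceeds 10% of the overall profile
mean. The difference is signed — a bright centre can never qualify.
Nuclei with zero overall γH2AX are reported UNIFORM with a QC flag
rather than erroring the field.

The foci test runs first; only non-foci nuclei enter the ring/uniform
split, which makes the phenotypes mutually exclusive and exhaustive by
construction and prevents a field of bright peripheral foci from being
read as a ring.

**Colocalization.** Pearson product-moment correlation between γH2AX
and 53BP1 intensities over the member pixels of each nucleus, on raw
intensities (no background subtraction). Undefined — flagged, not an
error — when either channel is constant within the nucleus or the
nucleus has fewer than 10 px. Computed for every accepted nucleus when
a 53BP1 channel is present; downstream filtering (e.g. to foci-positive
nuclei) is left to the user.

## Parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| `gaussian_sigma_px` | 2.0 | px | noise suppression ≪ nucleus radius |
| `struct_radius_px`, `n_dilations`, `n_erosions` | 3, 2, 2 | px, — | closes chromatin texture gaps without merging neighbours ≥ 20 px apart |
| `min_area_px` | 400 | px² | published screening value |
| `max_eccentricity` | 0.8 | — | published screening value |
| `min_circularity` | 0.85 | — | published screening value |
| `intensity_median_factor` | 2.0 | — | published screening value |
| `adaptive_window_px`, `adaptive_rel_offset` | 15, 0.15 | px, — | implementation defaults (see above) |
| `min_focus_area_px` | 4 | px | single-pixel noise guard |
| `foci_density_cutoff` | 0.0035 | px⁻² | published screening value; pixel-size dependent |
| `ring_rel_threshold` | 0.10 | — | published screening value |

The smoothing, morphology and adaptive-threshold settings were fixed
empirically in the original screening workflow and not published; the
defaults here are this package's own choices, and all are configurable.

## Phantom generator

The generator renders what the decision rules need to be exercised, at
realistic 20× geometry: non-overlapping ellipses with semi-axes drawn
from 18–45 px (areas ≈ 1000–6400 px²) and axis ratio ≤ 1.6, which caps
eccentricity at 0.78 — below the 0.8 filter, so a rejected phantom
nucleus in a recovery test indicates a bug, not a fixture. Raising
`axis_ratio_max` deliberately renders filter-violating objects for
adversarial tests.

Intensities are on a 16-bit scale: DAPI 2000 over background 100;
γH2AX nuclear base 2000 over a diffuse extranuclear background of 1600.
The dim-but-nonzero surround mimics residual antibody background and,
numerically, keeps the nucleus-boundary intensity step small enough
that a segmentation mask overshooting the true ellipse by a pixel
cannot make edge pixels clear the adaptive threshold under noise.
Per phenotype:

* UNIFORM — flat base;
* FOCI — base plus Gaussian puncta (σ = 2 px, amplitude 8000 = 4× base,
  the contrast of a clear focus over pan-nuclear staining). The count
  scales with the analytic ellipse area through a density drawn from
  0.005–0.0075 px⁻², safely above the 0.0035 cutoff; centres stay
  inside 0.8 of the radial coordinate with a pairwise separation
  relaxed stepwise from 12 px, so puncta remain resolvable in nuclei of
  any permitted size. (A fixed count range is available as an override;
  its lower bound is validated against the cutoff for the largest
  permitted nucleus.)
* RING — base ×2 in the outer 25% of the elliptical radial coordinate.
  The ideal two-level profile has ring score 0.8, checked analytically
  at construction (`analytic_ring_score`), so every RING phantom
  satisfies the quartile rule before noise.

Noise is shot noise (per-pixel Poisson resampling) and/or additive
Gaussian read noise, applied per channel with independent sub-seeds and
clipped to the bit-depth range. Identical specs and seeds produce
bit-identical images and tables.

What the phantom does **not** emulate: chromatin texture, the
microscope PSF, uneven illumination, touching or overlapping nuclei,
apoptotic morphology, and out-of-focus light. Passing recovery tests
therefore demonstrates that the measurement rules are implemented
correctly and are robust to photon/read noise at screening levels — not
that segmentation would survive confluent cultures, which would need
watershed splitting (out of scope).

## Numerical choices and degenerate inputs

* All arithmetic downstream of file reading is float64; intensities are
  never rescaled on read.
* Ray sampling uses ⌈distance⌉ + 1 equally spaced points (step ≤ 1 px),
  bilinear interpolation, `nearest` beyond the image edge.
* The quartile split index is clamped so both segments are non-empty
  for profiles shorter than 4 samples (only possible for degenerate
  nuclei far below the area filter).
* A constant DAPI field raises a degenerate-input error (no threshold
  exists); a field with zero accepted nuclei is a warning, not an
  error, and appears in summaries with undefined proportions.
* Nuclei smaller than 3 × 3 px or with fewer than 8 boundary pixels
  raise degenerate-nucleus errors in classification; they cannot occur
  downstream of the 400 px² area filter.
* Per-field proportions use accepted nuclei only; per-condition spread
  is the sample standard deviation (ddof = 1) across fields, undefined
  for a single field.
* CSV outputs have a fixed column order, mergesort-stable row ordering
  by (field_id, nucleus_id), `.` decimals and `\n` line endings, so
  identical inputs give byte-identical files.

## Validation

`scripts/acceptance.py` regenerates everything from scratch at a given
seed: a 60-nucleus field (20 per phenotype, 1024² px) analysed
noise-free and under shot + 5%-of-DAPI read noise, plus a 30-nucleus
colocalization phantom whose 53BP1 channel copies the γH2AX channel
before noise. Reported quantities: recovery percentages (noise-free
recovery is exact at the defaults; the noisy condition tolerates a few
misses per the test suite's 95% bound), recovered phenotype
proportions, mean ring score of RING nuclei, mean defined Pearson r,
and runtime per field (a few seconds per 1024² field on one CPU). The
problem sizes were chosen as the smallest at which all three phenotypes
appear in force across the permitted size range.

## Known limitations

* No splitting of touching nuclei; clumps typically fail the
  circularity or eccentricity filter and are excluded rather than
  resolved.
* The 0.0035 px⁻² foci cutoff and 400 px² area filter assume ~20×
  sampling; both must be rescaled for other pixel sizes.
* The ring rule reads any peripheral enrichment above 10% as RING,
  including biological look-alikes (e.g. apoptotic rim condensation);
  distinguishing those is a biological, not computational, exclusion.
* Pearson correlation is computed without background subtraction and is
  sensitive to shared gradients; Manders-style coefficients are out of
  scope.
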