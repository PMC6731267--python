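# ringtrack

Quantifying nuclear **γH2AX distribution phenotypes** in high-content
fluorescence microscopy.

Genotoxic stress marks chromatin with phosphorylated histone H2AX
(γH2AX). In screening images this signal appears in qualitatively
different spatial patterns: discrete **foci** (the canonical
double-strand-break response), a peripheral **ring** hugging the
nuclear envelope (a non-canonical pattern associated with
single-strand-lesion overload), or a **uniform** pan-nuclear haze.
`ringtrack` is an automated pipeline for 20× widefield screening data
that segments nuclei from a DAPI counterstain, assigns each nucleus
exactly one of the three phenotypes, measures per-nucleus γH2AX/53BP1
pixel colocalization, and aggregates phenotype proportions per
experimental condition. A synthetic phantom generator with per-nucleus
ground truth makes the whole pipeline testable without any microscope
data.

## Method

**Segmentation (DAPI channel).** Gaussian smoothing (σ = 2 px) →
automatic global threshold by exhaustive between-class-variance
maximisation on a 256-bin histogram (Otsu) → dilation, hole filling and
erosion with a disc → 8-connected component labelling. Candidate
objects are kept only if all four filters pass (strict inequalities):

| filter | rule |
|---|---|
| area | A > 400 px² |
| eccentricity | e < 0.8 (moment-matched ellipse) |
| shape regularity | 4πA/P² > 0.85 |
| intensity | mean DAPI < 2 × median over all candidates in the field |

**Foci test.** Within each nucleus the γH2AX signal is binarised with
an adaptive threshold: pixel *p* is focus-candidate iff
I(p) > (1 + α) · mean(window around *p*, nucleus pixels only), with
α = 0.15 over a 15 px window. 8-connected components of ≥ 4 px are
foci. The nucleus is **FOCI** iff

&nbsp;&nbsp;&nbsp;&nbsp;foci count / nucleus area > 0.0035 px⁻²

**Ring test** (non-foci nuclei only). Intensity profiles are cast from
the centre of mass to every boundary pixel, resampled to the length of
the longest ray and averaged. With the averaged profile split at ¾ of
the radial axis, the nucleus is **RING** iff

&nbsp;&nbsp;&nbsp;&nbsp;mean(last quartile) − mean(first three quartiles) > 0.10 × overall mean

and **UNIFORM** otherwise. The foci test runs first, so FOCI and RING
are mutually exclusive by construction. Both rules are intensity-ratio
based, hence invariant to exposure/gain rescaling.

**Colocalization.** When a 53BP1 channel is present, the Pearson
product-moment correlation between γH2AX and 53BP1 intensities is
computed over each nucleus's pixels (undefined and flagged for
constant channels or nuclei under 10 px).

## Worked example

Render a 30-nucleus synthetic field (10 per phenotype) and analyse it:

```bash
$ ringtrack simulate --n-nuclei 30 --seed 7 --out demo
wrote 30 nuclei to demo

$ ringtrack classify --dapi demo/dapi.tif --gh2ax demo/gh2ax.tif \
    --condition toxin_WT --out demo_out
30 accepted nuclei: UNIFORM=10, FOCI=10, RING=10
```

All 30 phantom nuclei pass the four filters and every phenotype call
matches the generator's ground truth (`demo/ground_truth.csv`). The
per-nucleus table shows the supporting metrics, e.g.

```
nucleus_id area_px eccentricity circularity foci_count foci_density ring_score phenotype
1          4668    0.166        0.925       0          0.0          -0.0001    UNIFORM
2          1954    0.415        0.929       10         0.00512                 FOCI
```

Nucleus 2 carries 10 detected foci over 1954 px² — density 0.00512 px⁻²
exceeds the 0.0035 cutoff, so it is FOCI and no radial profile is
computed. Nucleus 1 has no foci and a flat radial profile (ring score
≈ 0 ≤ 0.10), so it is UNIFORM.

Multi-field runs use a YAML config with an explicit plate map (condition
labels are never parsed from file names):

```yaml
fields:
  - field_id: A01_s1
    channels: {dapi: A01_s1_w1.tif, gh2ax: A01_s1_w2.tif, p53bp1: A01_s1_w3.tif}
plate_map:
  A01_s1: toxin_WT
```

```bash
ringtrack run --config run.yaml --out results/
```

writes `per_nucleus.csv` (fixed schema, deterministic bytes),
`summary_per_field.csv`, `summary_per_condition.csv`, one 16-bit label
mask TIFF per field, and `provenance.json` with all parameters and the
computed global thresholds.

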