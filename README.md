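# octaquant

Vessel-density quantification for en-face OCT-angiography (OCT-A) images.

The package implements a shape-prior-free analysis pipeline for 2D en-face
angiograms:

1. **Multi-scale feature bank** (`feature_bank`) — per-pixel Gaussian,
   gradient-magnitude, Laplacian, Hessian-eigenvalue and local-variance
   channels computed at physical scales (µm) spanning the expected
   vessel-diameter range, so the classifier can tell a true avascular
   region from the narrow interspace between small vessels.
2. **Trainable pixel classification** (`pixel_rf`) — a random forest fit
   on sparse avascular/vascular scribble annotations, producing a
   per-pixel avascular probability map and binary segmentation.
3. **ROI geometry** (`roi_geometry`) — extraction of the avascular core
   (largest 8-connected component, holes filled) and construction of
   peripapillary annulus masks at physical band widths
   (default 640 / 920 / 1960 µm) via exact Euclidean distance.
4. **Densitometry** (`densitometry`) — mean gray value and integrated
   gray-level density over any ROI or the whole image.
5. **Repeatability statistics** (`repeatability`) — coefficient-of-variation
   style relative fluctuation (100·sd/mean) of repeat series, percent
   differences between disease-stage means, and the
   truncation-at-printed-precision reporting convention.
6. **Cohort statistics** (`cohort_stats`) — a normality-gated routing
   between Student's t / one-way F test and Kruskal–Wallis, plus the
   Hoddap–Parrish–Anderson-style glaucoma staging rule from visual-field
   mean deviation.
7. **Synthetic phantoms** (`phantom`) — ground-truthed en-face angiogram
   phantoms (curvilinear vessel trees, disc/ellipse/irregular avascular
   regions, speckle noise, device brightness profiles) so the whole
   pipeline is testable without clinical data.
8. **Orchestration + CLI** (`pipeline`, `cli`) — deterministic end-to-end
   runs under a single seed.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (exact worked
examples plus phantom-based property suites).

## CLI

```sh
# generate a ground-truthed phantom with scribble annotations
octaquant phantom --out-dir scratch/ph --seed 1 --with-annotations

# train a pixel classifier from an image + annotation raster
octaquant train scratch/ph/phantom_disc_0001.png \
    scratch/ph/phantom_disc_0001_annotations.png \
    --model-out scratch/model.joblib --field-of-view-mm 3

# segment + measure densities (whole image, avascular core, 3 annuli)
octaquant density scratch/ph/phantom_disc_0001.png \
    --model scratch/model.joblib --out-dir scratch/run \
    --field-of-view-mm 3 --bands-um 640,920,1960

# fluctuation statistics of a repeat series stored as CSV
octaquant repeatability scratch/run/densities.csv --value-column mean_gray

# group comparison on a cohort density table
octaquant cohort cohort.csv --value-column density --group-column group
```

## Conventions

- Images are 8-bit range [0, 255]; higher bit depths are rescaled
  linearly on load. Pixel calibration is isotropic, derived from the
  declared field of view (µm/px = 1000 · FOV_mm / width_px).
- Masks are single-channel PNG (0/255); annotations are single-channel
  PNG with 0 = unlabeled, 1 = avascular, 2 = vascular.
- Reported fluctuation percentages are truncated (floored), not rounded,
  at the stated decimal precision; full-precision values are always kept.
- A single config seed governs all stochastic stages; identical inputs
  and seed reproduce byte-identical outputs.
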