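# Methods

## Problem and pipeline

`leafdist` analyses push-broom hyperspectral scans of single corn leaves to
assess nitrogen stress.  The conventional summary — the whole-leaf averaged
NDVI — discards how stress is distributed along the leaf, and high- and
low-nitrogen groups overlap heavily on it.  The pipeline instead extracts
the *distribution* of NDVI along the mid-rib and classifies treatments from
that profile:

1. **Calibration.**  Raw digital numbers are converted to reflectance
   against a white Teflon strip and a dark-current frame,
   `R_cali = (R_raw − R_dark) / (R_white + R_dark)`.  This denominator is
   the package default; the conventional flat-field form
   `(R_white − R_dark)` is available via
   `calibrate(..., denominator="white_minus_dark")`.  References are
   per-sensor-line (row × band) frames broadcast along the scan direction,
   matching how a line scanner is calibrated; full reference cubes are
   averaged over the scan direction first.  Storage is float32, computation
   float64.
2. **Segmentation.**  Each pixel's spectrum is linearly interpolated at 41
   equally spaced wavelengths across the red edge (680–720 nm) and dotted
   with the integer ramp kernel −20..20.  The kernel is zero-sum, so flat
   (background) spectra score exactly 0, while the red-edge rise of leaf
   tissue scores far above the default threshold of 7.  Interpolation is
   used because sensors differ in band spacing (the 0.74 nm-resolution
   instrument has ~54 bands in the window, not 41); a `nearest_bands` mode
   samples band centres directly instead.  No smoothing or morphology is
   applied by default; an optional largest-connected-component cleanup
   exists.  The threshold is a config value in reflectance·index units and
   presumes calibrated input.
3. **NDVI.**  Per leaf pixel, `(R_800 − R_650)/(R_800 + R_650)` with bands
   chosen by nearest wavelength (ties to the lower index).  Pixels with a
   non-positive denominator are invalidated rather than clipped so they
   cannot bias the leaf average.  Heatmaps use jet on a fixed 0–1 scale so
   images are comparable across leaves.
4. **Profiling.**  Valid pixels are averaged within each scan line (one
   value per mid-rib column), empty end columns are trimmed, interior holes
   are linearly interpolated (leaves with more than 20 % interior holes are
   rejected as low quality), and the variable leaf length L is rescaled to
   K = 50 sections.  Rescaling treats the raw profile as a step function on
   [0, L) and takes exact length-weighted means over K equal intervals —
   block means when L is divisible by K, mean-preserving in general.  Under
   these interval-mean semantics the order of "rescale" and "average into
   sections" does not matter, which is why that semantics was chosen.
5. **Classification harness.**  Four scikit-learn families run in
   regression mode against 0/1 treatment labels (1 = high N): AdaBoost,
   logistic regression (its class-1 probability is the continuous score),
   PLSR, and random forest.  One hyperparameter per family is grid-searched
   by 10-fold cross-validated RMSE: RF max depth 1–10, AdaBoost estimator
   count {10, 25, 50, 100, 200}, PLSR components 1–10, logistic C
   {0.01, 0.1, 1, 10, 100}; the other settings stay at scikit-learn
   defaults.  Ties break to the smallest candidate (the simpler model).
   Folds come from a seeded plain shuffle (a `stratify` option exists);
   every sample is validated exactly once and fold sizes differ by at most
   one.  Out-of-fold predictions are *not* thresholded — they are the
   quantity the evaluation layer t-tests, and out-of-fold (rather than
   refit-on-all) prediction is used because it is the non-leaking choice.
6. **Evaluation.**  Per method (averaged NDVI plus each model) the report
   gives group means, sample SDs (divisor n−1), and the two-sided
   pooled-variance two-sample t-test, expressed as −log10 p for treatment
   comparisons and as plain p for genotype comparisons; a Welch option
   exists.  KDE curves (Gaussian kernel, Scott's-rule bandwidth
   `h = sd·n^(−1/5)`, grid spanning the data ± 3 bandwidths) visualise group
   overlap.  The KDE is a direct kernel sum so that an explicit bandwidth
   and the zero-variance (single-atom) case are well defined.  No
   multiple-testing correction is applied across models.

## Synthetic scenes

No field imagery is available, so cohorts are simulated with known ground
truth.  A scene is an elliptical leaf mask tapering from collar to tip on a
flat dark background (878-pixel scan lines × 254 columns × 676 bands over
450–900 nm at full geometry).  Leaf spectra are parametric — flat red level,
flat NIR level (0.5), linear red-edge ramp between 680 and 720 nm — with the
red level solved per column so the pixel NDVI realises a target template;
this exercises every pipeline stage without radiative-transfer realism
(no PROSPECT-style modelling, device optics, motion blur or illumination
non-uniformity).  The emitted cube is raw DN folded through structured
white/dark reference frames, so calibration is a real inversion, exact to
float64 rounding at zero noise.

The NDVI template rises from the collar (exponential approach, scale 0.30
for high N / 0.15 for low N, amplitude 0.03 / 0.05) to a plateau and drops
quadratically past 90 % of the length (drop 0.12 / 0.18): high-N leaves sit
higher with a shallower rise and smaller tip drop.  Templates are centred
with elliptical-chord weights √(1−u²) so the whole-leaf *pixel* means of
noise-free leaves equal the arm targets: 0.845 (high N), 0.837 (low N), and
0.848 for an optional high-nutrient-efficiency genotype arm (smaller tip
drop, SD 0.008) used as a validation cohort.  Between-leaf variation has
two independent knobs: a level offset (SD 0.006 per arm) and relative
shape jitter (SD 0.2 on rise amplitude and tip drop); within-leaf
variation is i.i.d. per-band reflectance noise (SD 0.01).  These magnitudes
are the group-level statistics typical of nitrogen trials at this growth
stage; the true shape-versus-level split in real leaves is not identifiable
from group summaries, so the shape effect is an explicitly synthetic choice
tuned only to preserve the qualitative ordering (distribution models more
significant than the average).  Passing tests therefore show the pipeline
recovers what the generator encodes — they do not certify performance on
real leaf optics, specular artefacts, or non-elliptical leaves.

## Numerical and design notes

- **Geometry presets.**  `paperlike` (254 × 878 × 676) is the full
  acquisition geometry; `reduced` (64 × 878 × 100) keeps the full scan line
  at lower spectral/length resolution and is the default for single-cohort
  runs; `fast` (80 × 48 × 60) is used for replicated statistics.  Pixel
  noise only enters the profile after averaging hundreds of pixels per
  section, so the statistical behaviour is set by the level/shape knobs,
  not the geometry.
- **Determinism.**  All randomness flows from one top-level seed split into
  named substreams (cohort, folds, per-model), so stages are independently
  reproducible; fixed seeds give bit-identical cohorts, folds and (for the
  deterministic families) predictions.
- **Degenerate inputs.**  Zero calibration denominators, empty cubes,
  wavelength-count mismatches, single-class label vectors, zero pooled
  variance, and profiles shorter than two columns all raise explicit
  errors rather than propagating NaNs.
- **Orientation.**  Column 0 is the leaf collar (acquisition order); a
  `--flip`/`flip=True` option reverses profiles for scans taken tip-first.
  Inputs scanned with the long axis on the row dimension are transposed on
  load (`--transpose`).
- **Known limitations.**  Only the mid-rib (X) direction is profiled; the
  across-leaf direction is averaged out.  Only NDVI is validated, though
  any two-band normalized-difference index can be mapped.  Segmentation
  threshold 7 assumes calibrated reflectance; raw-DN input would need a
  rescaled threshold.  The elliptical mask has no petiole, lobes or damage
  beyond the hole-interpolation path.
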