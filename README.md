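# leafdist

Leaf-scale hyperspectral NDVI distribution analysis for nitrogen-stress
phenotyping.

Point measurements (SPAD) and whole-leaf averages hide how nutrient stress
is distributed across a corn leaf: chlorophyll and nitrogen vary severalfold
from collar to tip, and high- and low-nitrogen groups overlap heavily on
the averaged NDVI alone.  `leafdist` implements a pipeline for push-broom
hyperspectral leaf scans that keeps the spatial signal:

1. **Calibrate** raw counts to reflectance against white/dark references:
   `R_cali = (R_raw − R_dark) / (R_white + R_dark)`.
2. **Segment** leaf tissue by the red-edge convolution score: the spectrum
   over 680–720 nm, resampled at 41 points, dotted with the integer kernel
   −20..20; pixels scoring above 7 are leaf.
3. **Map NDVI** per pixel, `(R_800 − R_650)/(R_800 + R_650)`, with jet
   heatmaps on a fixed 0–1 scale, and the classical whole-leaf average
   `NDVI̅ = (1/n) Σ NDVI_pixel`.
4. **Profile** the mid-rib distribution: scan-line means, length rescaling,
   and 50 equal sections from collar to tip → one 1×50 feature vector per
   leaf.
5. **Classify** treatment (1 = high N, 0 = low N) from an N×50 cohort
   matrix with four regression-mode models (AdaBoost, logistic regression,
   PLSR, random forest), one grid-searched hyperparameter each, selected by
   10-fold cross-validated RMSE.
6. **Evaluate** with two-sample t-tests (−log10 p) and kernel density
   curves, comparing each model's out-of-fold predictions against the
   averaged NDVI.

Because no leaf imagery ships with the package, `leafdist.synthleaf`
generates full synthetic scenes (ENVI cubes, references, ground-truth masks
and profiles) whose group statistics mimic a real nitrogen trial
(whole-leaf NDVI means 0.845 vs 0.837, between-leaf SD 0.006); see
`docs/methods.md` for what the simulation does and does not capture.

## Worked example

```python
import numpy as np
from leafdist import (
    cohort_from_simulation, synthleaf, two_sample_ttest,
)
from leafdist.mlharness import ModelSpec, grid_search, crossval_predict

# 32 high-N + 32 low-N synthetic leaves through the full pipeline
data, avg_ndvi, manifest = cohort_from_simulation(
    32, synthleaf.preset("fast"), seed=1
)
print(data.features.shape)            # (64, 50)

spec = ModelSpec("random_forest", seed=1)
best_depth, _ = grid_search(data, spec)
cv = crossval_predict(data, spec, best_depth)

hi = data.labels == 1
t_avg = two_sample_ttest(avg_ndvi[hi], avg_ndvi[~hi])
t_rf = two_sample_ttest(cv.oof_predictions[hi], cv.oof_predictions[~hi])
print(f"averaged NDVI: means {t_avg.means[0]:.3f}/{t_avg.means[1]:.3f}, "
      f"-log10 p = {t_avg.neg_log10_p:.2f}")
print(f"random forest (depth {best_depth}): means "
      f"{t_rf.means[0]:.3f}/{t_rf.means[1]:.3f}, "
      f"-log10 p = {t_rf.neg_log10_p:.2f}")
```

Output:

```
(64, 50)
averaged NDVI: means 0.846/0.837, -log10 p = 6.52
random forest (depth 2): means 0.874/0.137, -log10 p = 18.13
```

The averaged NDVI separates the treatments (means 0.846 vs 0.837, ~1.3 SDs
apart), but the random-forest model trained on the 50-section distribution
profile pushes its out-of-fold predictions toward the 1/0 labels and
separates the same leaves far more significantly — the distribution carries
information the average throws away.

The same workflow is available from the shell:

```sh
leafdist simulate --scenario fast --n-per-group 32 --seed 1 --out scratch/sim
leafdist process  --in scratch/sim  --out scratch/proc
leafdist profile  --in scratch/proc --out scratch/cohort.csv
leafdist evaluate --cohort scratch/cohort.csv --seed 1 --out scratch/eval --plots
```

`evaluate` prints the comparison table (one row per method: group means,
SDs, −log10 p) and writes it as CSV/JSON together with KDE curves and
cross-validation records.

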