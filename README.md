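# neuromorph

Machine-learning-assisted morphometry of peripheral-nerve histology.

After limb amputation or nerve transection, the proximal stump can form a
neuroma — a disorganized mass of regenerating mini-fascicles and connective
tissue — and some, but not all, neuromas are painful. One structural
hypothesis is that the amount of *preserved, organized fascicular tissue*
inside the lesion buffers against neuropathic pain. Testing it requires
quantifying tissue composition across whole histology sections, which is
what this package does:

1. **Pixel classification.** A random forest over ilastik-style color /
   smoothing / gradient / local-variance features (4 Gaussian scales, 39
   channels) labels every pixel of an EvG-stained section as one of six
   classes: background, organized nervous tissue, unorganized nervous
   tissue, connective tissue, adipose tissue, or erythrocytes. The output
   is a per-pixel 6-channel probability map.
2. **Fascicle shape filtering.** Connected nervous-tissue components are
   re-labeled wholesale by circularity `C = 4πA/P²` (perimeter from a
   smoothed sub-pixel boundary): components with `C ≥ 0.6` are organized
   fascicles, the rest are neuroma tissue.
3. **Composition and the normalized deviation index.** Per sample, absolute
   (mm²) and relative areas per class, plus

   ```
   index = (unorganized − organized) / max(unorganized, organized)
   ```

   which is −1 when only organized nervous tissue is present, +1 when only
   unorganized tissue is present, and undefined when there is neither.
4. **Cohort statistics.** Lilliefors-gated group comparisons (Student's t
   or exact Mann–Whitney U), and tie-corrected Spearman correlations of
   composition against the NRS pain score, with violin/scatter figures.

Because the original slides are clinical data, the package ships a
**synthetic cohort generator** that renders EvG-like nerve cross-sections
with pixel-exact ground truth, emulating a 12-sample cohort (4 control
nerves, 3 non-painful neuromas with NRS 0, 5 painful neuromas with NRS
[5, 6, 7, 8, 8]) in which painful samples carry a lower fraction of
organized fascicles. Every downstream stage is tested against this ground
truth.

## Worked example

```python
import neuromorph as nm
from neuromorph.pipeline import PipelineConfig, run_pipeline

spec = nm.default_cohort_spec(image_size=256, seed=0)
result = run_pipeline(spec, PipelineConfig())

acc = min(result.pixel_accuracy.values())
org = result.report.find("relative_organized_nervous", "vs_nrs")
dev = result.report.find("deviation_index", "vs_nrs")
print(f"min pixel accuracy  {acc:.4f}")
print(f"organized vs NRS    rho={org.statistic:+.3f}  p={org.p_value:.2e}")
print(f"deviation vs NRS    rho={dev.statistic:+.3f}  p={dev.p_value:.2e}")
```

prints

```
min pixel accuracy  0.9988
organized vs NRS    rho=-0.970  p=6.74e-05
deviation vs NRS    rho=+0.970  p=6.74e-05
```

meaning: the classifier recovers ≥ 99.9 % of ground-truth pixels on every
sample, the relative amount of organized nervous tissue falls monotonically
with reported pain across the 8 neuroma samples (negative Spearman rho),
and the deviation index rises with pain — the directions the pipeline is
built to detect. `examples/` contains one short script per capability
(simulation, training/segmentation, morphometry, statistics, full
pipeline).

A thin CLI wraps the same stages:

```sh
neuromorph simulate --seed 0 --out cohort/
neuromorph train --images cohort/ --seed 0 --out model.joblib
neuromorph segment --model model.joblib --image cohort/P01_image.png --out-labels P01_pred.png
neuromorph quantify --mask P01_pred.png --mpp 0.5
neuromorph run-all --seed 0 --out run/
```

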