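# haloseg

Segmentation of unstained, live stem cells in phase-contrast microscopy
images, with automatic confluency estimation.

Phase-contrast optics make transparent cells visible without staining, but
they surround every cell with a bright **halo artifact** whose intensity
rises away from the cell and falls back to background just outside the true
boundary. Plain thresholding therefore either misses the low-contrast cell
bodies or swallows the halo annulus. `haloseg` implements a classical,
fully interpretable pipeline for this setting:

1. **Local-contrast preprocessing.** The gray image *I* is mapped to
   `C = (w∗I² − (w∗I)²) / (w∗I)` with a 3×3 Gaussian window *w* — the
   Gaussian-weighted local variance over the local mean. Textured cell
   bodies and halo edges score high; flat background scores near zero.
2. **Adaptive thresholding.** From the integer-binned histogram of *C* two
   features are read: the peak position *Mp* and the rate of rise *β* (the
   steepest slope on the ascent to the peak). With a per-dataset adjustment
   *k*, exponent *l* = 2, and the dataset maximum rate of rise *βᵤ*, the
   threshold is

   `T = Mp + k · (Mp²/255) · (β^l / βᵤ − 1)`

   so *Mp* acts as the reference point and the correction adapts to how
   peaked each image's distribution is. Binarization (`C ≥ T`) is followed
   by an area constraint (small components removed, small holes filled).
3. **Halo correction.** The coarse contour is walked along the halo's
   radial intensity profile using gradients in eight directions (the four
   axial and four diagonal neighbors); a contour point keeps moving while
   the gradient in its direction of travel is positive and freezes when it
   turns negative — i.e. at the halo ridge next to the true cell boundary.
4. **Evaluation & confluency.** Pixelwise accuracy, recall, precision and
   F1 against reference masks, plus confluency = foreground area fraction
   `(TP+FP)/(TP+FP+TN+FN)` and its absolute error against a
   staining-derived standard value.

A seeded **synthetic phantom generator** renders phase-contrast-like scenes
(dark textured cell bodies, cosine-tapered halo ridges, illumination tilt,
sensor noise) with exact ground-truth masks, so the entire pipeline is
testable without any external data.

Intended users: cell-culture labs and imaging-core engineers who need fast
(~seconds per image), transparent confluency monitoring on ordinary CPUs,
and method developers who want a reproducible classical baseline.

## Worked example

Generate three phantoms at ~30 % confluency, segment them with the default
(phantom-calibrated) profile, and evaluate against the ground truth:

```sh
haloseg simulate --out demo --n-images 3 --seed 7 --target 0.3
haloseg segment demo/phantom_000.png demo/phantom_001.png demo/phantom_002.png --out demo/masks
haloseg evaluate --pred-dir demo/masks --truth-dir demo --out demo/metrics.csv
```

which prints, per image, the fitted histogram features, the threshold and
the estimated confluency:

```
phantom_000.png: beta=30.887 Mp=3 T=5.042 iterations=20 confluency=0.3141 (0.04s)
phantom_001.png: beta=29.660 Mp=3 T=4.876 iterations=20 confluency=0.3490 (0.05s)
phantom_002.png: beta=30.215 Mp=3 T=4.951 iterations=20 confluency=0.3347 (0.04s)
{
  "mean_accuracy": 0.94293212890625,
  "mean_recall": 0.9645093123751808,
  "mean_precision": 0.8605911362781772,
  "mean_f1": 0.9094140522399203,
  "mean_confluency": 0.3326263427734375,
  "mean_error": null
}
```

`beta`/`Mp` are the per-image histogram features, `T` the adaptive
threshold on the rescaled contrast field, and `confluency` the predicted
cell-covered area fraction (the scenes were built at 0.30–0.35 true
confluency). The evaluate step writes a per-image CSV plus a JSON summary;
`mean_error` is null because no staining-derived standard confluency was
supplied.

For real data, use the published dataset profiles instead of the phantom
default, e.g. `haloseg segment *.tif --out masks --profile c2c12`, or fit
your own profile from annotated pairs with `haloseg calibrate`.

The library mirrors the CLI one-to-one:

```python
from haloseg import PhantomConfig, generate_scene, segment_image

scene = generate_scene(PhantomConfig(seed=7))
result = segment_image(scene.image)
print(result.threshold, result.confluency)
```

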