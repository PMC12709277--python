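# Methods

## Model and procedure

`haloseg` segments phase-contrast images of adherent cells in four stages.

**Local contrast (preprocessing).** The gray image `I(x, y)` is convolved
with a normalized 3×3 Gaussian window `w` (σ = 0.8 by default) and mapped to

    C = (w∗I² − (w∗I)²) / (w∗I + ε),   ε = 1e−6,

the Gaussian-weighted local variance divided by the local mean. This
grouping is the only parse of the expression that is dimensionally a
contrast and non-negative; the ε stabilizer only matters in black regions,
where it makes `C = 0` instead of 0/0. Borders use edge-duplicating
reflection. `C` is homogeneous of degree one in the intensity
(`C(sI) = s·C(I)`), so its absolute scale carries no information; before
histogramming, the pipeline linearly rescales `C` so that its 99.5th
percentile maps to 255 (values above are clipped). That puts the
integer-binned histogram on a stable, exposure-free 0–255 working range —
without it, typical contrast values of a few units would collapse into one
or two integer bins and the histogram features below would be degenerate.

**Adaptive threshold.** From the integer-binned histogram of the rescaled
contrast field, smoothed with a centered moving average (width 5 bins),
two features are extracted: the peak bin `Mp` (ties broken toward the
lowest bin) and the rate of rise `β`, the maximum forward difference of
the smoothed histogram over the ascending segment from the first nonzero
bin up to `Mp`, normalized per 1000 pixels. A degenerate histogram
(single bin, or peak at the first occupied bin) yields `β = 0`. The
threshold is

    T = Mp + k · (Mp²/255) · (β^l / βu − 1),   l = 2,

clamped to `[0, max(C)]` before use. `Mp` is the reference point: images
whose rise rate satisfies `β² = βu` are thresholded exactly at the peak;
weaker rises pull `T` below it, stronger rises push it above. The
correction-term grouping is isolated in a single function
(`threshold.estimate_threshold`) so the alternate dimensionless reading
`(β/βu)^l` can be swapped in if a deployment's parameter scale requires it.
`k` (dimensionless) and `βu` (the maximum per-image `β` over a dataset)
are dataset properties; see *Calibration*.

Binarization keeps `C ≥ T` (cells and halo edges are the high-contrast
class), then an area constraint removes 4-connected foreground components
below `min_area` (default 64 px) and fills enclosed background holes below
`fill_holes_below` (default 64 px).

**Halo correction.** In phase contrast, intensity along a ray from the
background toward a cell rises through the halo to a ridge and falls at
the true boundary. The coarse high-contrast mask covers that entire bright
annulus, so its contour sits at the halo's *outer* edge; the default
correction therefore peels the contour inward ("shrink"), ascending the
ramp, using gradients to the eight neighbors. A contour point is removed
while some interior neighbor is brighter by more than `gradient_epsilon`;
a point whose inward gradients are all below the margin has reached the
ridge and freezes permanently. Iteration stops when every point is frozen
or after `max_iterations` (default 20, a safeguard — the correction
distance is bounded by the halo width in practice). The symmetric "grow"
mode (outward region growth from an under-covering contour) is available
via configuration. Three guards make the shrink robust:

- gradients are evaluated on the raw gray image (whose profile the
  stopping rule describes), lightly smoothed (`gradient_smooth_sigma`,
  default 1.5 px), so single-pixel noise does not move the contour;
- `gradient_epsilon` (default 5 gray levels) must exceed both the noise
  gradient scale and the intra-layer intensity spread of a discretized
  ramp (roughly slope × 0.5 px), otherwise the peel rolls past the ridge;
- only the exterior contour participates: boundaries of interior holes
  and pixels on the image border (cells clipped by the field of view have
  no halo ridge there) never seed or join the peel front. Without the
  border exclusion, peel fronts enter clipped cells and wander through
  interior texture indefinitely.

**Evaluation and confluency.** Pixelwise confusion counts give accuracy
`(TP+TN)/N`, recall `TP/(TP+FN)`, precision `TP/(TP+FP)` and their
harmonic mean F1. Ratios with zero denominator are reported as undefined
(`None`), distinct from zero, and excluded from aggregate means (the
summary records how many were excluded); both per-image means and
pooled-pixel metrics are emitted. Confluency is the predicted foreground
area fraction; its headline error against a staining-derived standard is
the absolute difference (the signed difference is retained for
diagnostics, since reported errors are conventionally positive scalars).

## Calibration

`βu` is the maximum per-image `β` over an annotated calibration set. `k`
is fitted by exhaustive grid search, maximizing mean per-image pixel F1 of
the *full* pipeline over the calibration pairs, ties broken toward the
smallest `k`; `l` stays fixed at 2. The shipped profiles are:

| profile   | k    | βu      | Mp  | source                                  |
|-----------|------|---------|-----|-----------------------------------------|
| `c2c12`   | 0.86 | 30.99   | 276 | published benchmark parameters          |
| `hmscs`   | 1.68 | 27.45   | 209 | published benchmark parameters          |
| `phantom` | 2.5  | 39.5081 | 3   | `calibrate()` on ten default phantoms (seeds 1000–1009, confluency 0.1–0.5, k grid 0.5–3.0 step 0.5) |

`Mp` is estimated per image by default; a profile's `Mp` is applied only
when explicitly pinned (`--fixed-mp` / `fixed_m_p`), for deployments that
prefer one dataset-level reference. Note the phantom profile's feature
scale differs from the published profiles': the β normalization that
produced the published values is not recoverable, so parameters are not
transferable across scales — each imaging setup should be calibrated.

## Synthetic phantom generator

Scenes place `n_cells` (default 8) radially perturbed elliptical cells
(radii 12–24 px by default, boundary perturbed by random Fourier harmonics
2–5 scaled to ±`shape_irregularity` = 0.25) on a 256×256 field; overlaps
merge in the ground-truth mask. Intensity is rendered from the signed
distance to the nearest true boundary: interior plateau at
`cell_intensity` (0.75) × `background_level` (120), a cosine rise starting
`ramp_inside` (2 px) inside the boundary to a ridge of `halo_peak_gain`
(1.5) × background at `halo_width`/2 (2 px) outside, and a cosine decay
back to background by `halo_width` (4 px). Cell interiors carry smooth
multiplicative texture (`cell_texture` = 0.15 relative amplitude,
correlation `texture_scale` = 1.5 px) emulating organelle-scale structure —
this is what makes cell bodies visible to the local-variance contrast, as
they are in real phase-contrast images. A planar illumination tilt
(±5 % across the field, 10 % total span) and Gaussian sensor noise
(σ = 3 gray levels) are added last; output is 8-bit. All draws come from a
single seeded generator, so identical configs reproduce bit-identical
scenes. Dataset generation can hit requested confluency targets to ±0.03
by bisecting a global radius scale.

What the phantoms deliberately do **not** model: Zernike optics (the halo
is a geometric ridge, not a diffraction pattern), shade-off inside large
cells, mitotic brightening, debris, vignetting beyond a planar tilt, and
Poisson shot noise. Passing tests on phantoms therefore demonstrate the
pipeline's mechanics (feature extraction, threshold adaptation, ridge
recovery, confluency accounting), not performance on any real dataset;
real deployments should calibrate and spot-check against annotated images.

## Numerical choices and degenerate inputs

- Histogram bins: nearest-integer binning of the (non-negative) working
  field; smoothing uses zero-padded convolution, so edge bins are damped
  symmetrically.
- Peak ties break toward the lowest gray level; `β ≥ 0` by construction.
- `T` is clamped to `[0, max(C)]`; an all-zero image yields `C = 0`,
  `β = 0`, and an all-foreground mask only if `T` clamps to 0.
- Area constraint uses 4-connectivity for both components and holes;
  border-touching background is never treated as a hole. The operation is
  idempotent.
- Halo correction uses 8-connectivity for movement and 4-connectivity for
  contour membership; out-of-bounds neighbors read as −∞ gradient. Grow
  mode adds at most one chessboard ring per iteration, so the corrected
  band is at most `max_iterations` thick.
- Ties and simultaneity: all mask updates within an iteration are
  simultaneous (layer-parallel), making results order-independent and
  reproducible.
- Scene rendering quantizes to 8-bit after noise; determinism holds at the
  stored-image level across platforms.

## Problem sizes in tests

The test suite and the acceptance script run entirely on synthetic data:
ten 256×256 scenes spanning confluency 0.1–0.5 for end-to-end quality and
the preprocessing ablation, five scenes for calibration recovery, 8×8
images against the brute-force contrast oracle, 16×16 mask pairs against
the per-pixel metric oracle, and a 64×64 radial ridge scene for halo
recovery. These sizes keep every stage's behavior measurable while a full
run stays in the tens of seconds on one CPU.

## Known limitations

- The coarse threshold is global per image; strong local illumination
  structure beyond a smooth tilt can defeat it.
- The corrected contour sits at the halo ridge, slightly outside the true
  boundary (half the halo width); confluency is correspondingly biased
  upward by a thin perimeter band, most visible for small cells.
- Touching cells are segmented as one region (pixel-level evaluation
  only; no instance splitting).
- High-confluency fields (≳ 0.7) leave little background for the rescale
  percentile and histogram peak to anchor on; parameters fitted at
  moderate confluency may need refitting.
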