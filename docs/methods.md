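# Methods

This note records the models, conventions, numerical choices and known
limitations behind `rbcmorph`. The package analyses bright-field micrograph
sequences of red blood cells (RBC) suspended in a viscous medium under
shear, and reports per-frame counts of intact cells and fragments, per-cell
shape-asymmetry scores and elongation indices, and the asymmetric-cell
fraction over time.

## Image model and preprocessing

Frames are processed in floating point on the 8-bit scale [0, 255] and
quantized only on export. The assumed optics are halogen bright-field at
40×: a bright, smoothly varying background with cells appearing as
dark-rimmed ellipsoids and fragments/vesicles as small dark particles.

The per-frame chain is: rolling-ball background correction → percentile
contrast stretch → Sobel gradient magnitude → Gaussian smoothing of the
edge map → affine rescale of the map to [0, 255].

- **Rolling ball** (`ball_radius`, default 80 px): rolled on the inverted
  image (bright background), with the ImageJ-style shrink/upscale speed-up
  for large radii (block-minimum downscale, small-radius roll, bilinear
  upscale, clipped under the surface). The radius must exceed the largest
  cell diameter so the ball cannot enter cell footprints; 80 px covers the
  ~75 px worst-case two-lobe cell at the fixture scale.
- **Contrast stretch** (`saturation_fraction`, default 0.0035): the
  (q, 1−q) intensity quantiles map linearly to (0, 255) — the common
  micrograph normalization; monotone in intensity; constant frames pass
  through with a warning.
- **Sobel**: the standard 3×3 kernels, reflective borders, magnitude
  √(Gx²+Gy²).
- **Gaussian smoothing** (`sigma`, default 5 px) is applied to the
  edge-magnitude map — its role is to suppress small noise particles before
  counting, which places it after edge detection; applying it to the
  intensity frame instead is supported via `smooth_before_edges`.
- **8-bit rescale** of the smoothed map fixes the scale on which the
  prominence threshold is expressed (the conventional convert-to-8-bit
  step: data min/max to 0/255).

## Detection

Objects are counted as local maxima of the smoothed edge map accepted when
they rise at least `min_prominence` (default 50) grayscale units above both
the frame's noise floor (the map median) and their topographic key saddle
(true prominence). Prominence for all candidates is computed exactly in one
union-find superlevel-set persistence sweep (8-connected, numba-compiled);
a per-peak grayscale-reconstruction implementation of the same definition
is retained as the reference.

With σ = 5 smoothing, a cell rim at this scale produces an annular or
apex-dominated response whose raw maximum can sit on the rim rather than at
the cell centre. Accepted peaks are therefore refined to the
magnitude-weighted centroid of their connected superlevel region at level
(noise floor + `min_prominence`/2): that region is the whole rim response,
so the refined point lands on the cell centre (≤ 0.4 px on clean synthetic
frames), and duplicate maxima on one rim refine to the same point and are
merged by the `min_distance` suppression (default 20 px; highest prominence
wins, ties by lower (row, col)).

Detected objects are cropped (`crop_window`, default 128 px — at least
twice the largest expected cell major axis; border-truncated crops are
tallied and excluded), binarized, and split by footprint area:
`min_cell_area` (default 200 px²) separates intact cells (≳ 700 px² at the
fixture scale) from fragments/vesicles (≲ 40 px²). Fragments are counted
per frame but not scored.

## Per-cell morphometry

- **Binarization**: Otsu's histogram threshold on the crop (cells are
  dark → foreground is sub-threshold); the connected component nearest the
  detection point is kept, interior holes filled, centroid = foreground
  centre of mass.
- **Apex alignment**: the principal axis from second-order central moments
  is made vertical, and of the two vertical poses the one with the farther
  major-axis extreme (the apex) pointing up is chosen. Masks with inertia
  eigenvalue ratio < 1.02 are isotropic (no meaningful axis) and are
  flagged instead of rotated. For scoring, the aligned-frame radial profile
  is obtained by casting rays at offset angles on the *unrotated* mask —
  mathematically identical to profiling the rotated raster but free of
  resampling error; the rotated raster is still produced for the
  elongation-index extents.
- **Radial profile**: for each integer degree (counterclockwise, 0° to the
  right, apex at 90°), rays march from the centroid in 0.25 px steps on the
  bilinearly interpolated mask; the radius is the first 0.5-crossing,
  located sub-pixel by linear interpolation. The first background crossing
  is used (innermost boundary) so mild concavities are handled; a cell
  whose centroid falls outside its own foreground is flagged invalid.
  Pointwise, a binary mask localizes its boundary only to ~0.5 px, so
  per-degree radii carry that quantization noise; the profile is unbiased,
  and the scalar score averages most of the noise out.
- **Area normalization**: radii are divided by the equivalent-circle radius
  √(area/π). The asymmetry score is a ratio of areas under the same curve
  and is therefore exactly unchanged; normalization exists so profiles are
  comparable across magnifications, shear-induced elongations and cell
  volumes.

### Nadir search and score

The radius-vs-angle curve of an elongated cell is bimodal (peaks at the two
apexes). The curve is split at a starting minimum and at the central nadir,
and the score is |(A₁ − A₂)/A₁| × 100 with A₁ the trapezoidal area of the
half traversed first (counterclockwise from the start) and A₂ the
remainder; areas use the unsmoothed profile with fractional-angle endpoints.

Locating the split is the numerically delicate step: the valleys of the
profile are flat, the bare argmin moves by degrees under ~0.1 px of
boundary error, and the score responds at ~0.75 percentage points per
degree of split displacement. The implementation therefore:

1. low-passes the profile to its first 8 circular harmonics (enough for
   the bimodal structure, suppresses pixel-quantization wiggles);
2. takes each local minimum's **valley centre**: the depth-weighted angular
   centroid of the connected region below (valley minimum + 0.35 × profile
   range) — a level deep enough to absorb low-pass ringing bumps and
   shallow enough never to cross the main peaks; minima separated only by
   ringing share a region and collapse to one valley;
3. chooses the start valley among those tied within 2% of the profile range
   of the deepest, as the one nearest the 0° direction of the aligned
   frame. Mirror-symmetric cells have two exactly-tied valleys, and this
   tie-break pins the half-curve ordering reproducibly;
4. takes the central nadir as the deepest valley whose centre lies in
   (start + 90°, start + 270°).

Profiles with fewer than two low-passed maxima or peak-to-peak variation
below 2% of the mean radius (near-circular cells) are not bimodal: the cell
is flagged invalid and excluded rather than scored.

The same convention is implemented independently on continuous geometry in
`rbcmorph.analytic` (exact centroids, bisection ray casting at 0.1°), which
serves as the oracle: raster-pipeline scores agree with it to well under
one percentage point for cells ≳ 25 px semi-major, and the score is
invariant to rotation and scale at the ≤ 0.5 percentage-point level.

- **Elongation index**: EI = (A − B)/(A + B) with A the vertical and B the
  horizontal extent of the aligned mask (extreme-pixel distances). Measured
  on the binary mask; accurate to ±0.02 down to 10 px semi-axes.

## Classification and reporting

The decision threshold is x̄ + 2σ (sample sd, n − 1) of the scores of a
reference population asserted normal; `AsymmetryThresholdClassifier` wraps
this as a scikit-learn estimator. Classification is strict: a score equal
to the threshold is symmetric. For a Gaussian-like reference population the
expected false-positive rate on normal cells is the one-sided 2σ tail,
≈ 2.3%; reported asymmetric fractions are inflated by roughly that amount.
A published calibration of this method (2.77%, healthy ellipsoidal cells at
60 Pa) ships as the constant `REFERENCE_THRESHOLD` — it is specific to that
optical setup and population, so it is a preset, never a silent default.

Frame summaries report counts, the asymmetric fraction as a percent of the
frame's scored cells (0 with a `no_cells` flag for empty frames), mean and
median EI, and time = frame_index / fps (default 10 frames s⁻¹, the
acquisition rate the pipeline assumes). `detect_onset` estimates the onset
frame of an elevated regime by maximum-likelihood single-change-point
fitting — binomial likelihood when per-frame counts and cell totals are
given, two-segment least squares on fractions otherwise. At 8 cells per
frame the change point is intrinsically resolvable to ±2 frames in only
~90% of random sequences (a frame drawing zero asymmetric cells right
after onset is indistinguishable from baseline).

## Synthetic data

The generator emulates what the pipeline assumes and nothing more:

| parameter | default | rationale |
|---|---|---|
| frame size | 448 × 448 px | field holding ~10 well-separated cells |
| background / gradient | 200 / 25 gray | bright field with illumination ramp |
| edge drop / interior | 120 / 45% of drop | dark 2 px rim, lighter interior |
| noise sd | 3 gray | sCMOS-like sensor noise on 8-bit scale |
| cell semi-major | U(22, 27) px | ~11 µm sheared RBC at 40× sampling |
| aspect ratio | U(1.7, 2.3) | EI ≈ 0.26–0.39, ellipsoids in 30 mPa·s medium |
| lobe factor (asymmetric) | 1.5 | clearly but not grossly deformed |
| fragment semi-major | U(2, 3.5) px | ~1 µm vesicles/fragments |
| cells / fragments per frame | 8 / 2 | dilute (200×) suspension |
| min separation / margin | 85 / 68 px | isolated cells, untruncated crops |
| fps | 10 | acquisition rate |

The "abnormal" cell model is a two-lobe composite — two half-ellipses
sharing the minor axis, the apex side scaled by the lobe factor λ ≥ 1 —
chosen because it reduces exactly to an ellipse at λ = 1, has closed-form
centroid and area, and gives the analytic score oracle a continuous shape
family with monotone asymmetry. Per-frame cell kinds are independent
Bernoulli draws from the schedule, and the ground truth records realized
counts. Seeded generation is bit-reproducible.

What the generator does **not** emulate: cell overlap and clumping (cells
are placed with a minimum separation; overlapping cells are only flagged),
motion blur, defocus and halo rings, echinocyte spicules, tumbling
(3-D pose), or photobleaching. Passing tests therefore demonstrate
correctness of the measurement chain on well-formed, isolated, in-focus
cells — not robustness to crowded or degraded recordings.

## Degenerate inputs and tie-breaks

Constant frames pass background correction flat and contrast-stretch
unchanged (warning); empty or flat edge maps yield zero detections; cells
touching the crop border are tallied, not scored; empty-foreground crops,
non-bimodal profiles, and centroids outside the foreground are flagged and
counted as skipped, never aborting a run. Detection ties (equal prominence)
resolve to the lower (row, col); nadir ties resolve toward the 0° direction
as above; the elongation index orders axes so A ≥ B.

## Known limitations

- Scores are quantization-limited below ~15 px semi-major; at the published
  cell scale the symmetric-cell score noise is ~0.5 pp sd, which is what
  the x̄ + 2σ calibration absorbs.
- The detection guarantees assume separations above `min_distance` and
  rims that do not merge after σ = 5 smoothing (≈ 85 px centre-to-centre at
  the fixture scale); crowded fields undercount.
- No tracking: counts are per-frame, so the same physical cell is counted
  in every frame it appears in, exactly as in per-frame fraction reporting.
- The two-lobe family is a stand-in for real aberrant morphologies, which
  are more varied; the score itself is shape-agnostic, but synthetic recall
  numbers apply to that family only.
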