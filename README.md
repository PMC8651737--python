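# rbcmorph

Morphometric detection of asymmetric red blood cells (RBC) in viscous shear
flow, from bright-field micrograph sequences.

RBC exposed to supraphysiological shear stress (tens of Pa, as inside
ventricular assist devices and oxygenators) accumulate sublethal membrane
damage before any haemoglobin is released. In a viscous medium a healthy RBC
deforms into a symmetric ellipsoid; a structurally compromised one deforms
asymmetrically, and fragments/extracellular vesicles appear. Classical
deformability readouts such as the elongation index are insensitive to a small
damaged subpopulation, while a per-cell *shape-asymmetry* score separates it
cleanly. `rbcmorph` implements that analysis for researchers studying
shear-induced blood trauma: it counts cells per video frame, scores each
cell's shape asymmetry, and reports the asymmetric-cell fraction over time.

## Method

Each frame is background-corrected (rolling ball), contrast-stretched, passed
through a Sobel edge detector, and the edge-magnitude map smoothed with a
Gaussian (σ = 5 px). Cells and fragments are counted as local maxima of the
smoothed edge map with topographic prominence ≥ 50 (8-bit scale). Each
detected cell is cropped, binarized (Otsu), and rotated so its apex points up;
the radius from the centroid to the cell edge is then measured for every
angular degree counterclockwise, and divided by the equivalent-circle radius
√(area/π) so the profile is independent of magnification and cell size.

For an elongated cell this radius-vs-angle curve is bimodal. It is split at
its central nadir into two half-curves with areas A₁ and A₂, and the
asymmetry score is

    score = |(A₁ − A₂)/A₁| × 100   [percent]

which is zero for a perfectly mirror-symmetric cell. Deformability is
summarized per cell by the elongation index EI = (A − B)/(A + B) from the
major (A) and minor (B) axis extents.

A decision threshold is calibrated as x̄ + 2σ of the scores of a reference
population of cells asserted normal (e.g. a low-shear control recording);
cells scoring strictly above it are classified asymmetric, and each frame
reports total cells, fragments (objects below the intact-cell area), the
asymmetric fraction as a percent of cells in that frame, and ensemble EI.

Because no public micrograph data exist for this assay, the package includes
a first-class synthetic-frame generator (`rbcmorph.synthetic`) producing
ground-truthed bright-field-like sequences: dark-rimmed ellipsoidal cells,
two-lobe asymmetric cells (two half-ellipses sharing the minor axis, with a
closed-form oracle in `rbcmorph.analytic`), fragments, illumination gradients
and sensor noise.

## Worked example

```sh
# a control recording of symmetric cells, with ground truth
rbcmorph synth --out control.tiff --n-frames 6 --seed 11
# calibrate the mean + 2σ threshold on it
rbcmorph calibrate --frames control.tiff --out calibration.txt
# a "damaged" recording: each cell has a 25% chance of being asymmetric
rbcmorph synth --out sheared.tiff --n-frames 6 --asymmetric-fraction 0.25 --seed 12
# analyze it with the calibrated threshold
rbcmorph analyze --input sheared.tiff --calibration calibration.txt --out report
```

prints

```
calibrated on 48 cells: mean 0.720%, sd 0.601%, threshold 1.922%
analyzed 6 frames: mean cells/frame 8.0, mean asymmetric fraction 29.17%
```

The calibration line says the 48 control cells scored 0.72% ± 0.60%
(mean ± sd), so the symmetric/asymmetric boundary is 1.92%. The analysis line
is the time-series average: with a 25% asymmetric-cell probability per cell,
the per-frame fractions scatter binomially around ~25% plus the ~2% expected
false-positive rate of a 2σ threshold. `report/per_frame.csv` holds the
per-frame time series:

```
frame_index,time_s,n_cells,n_fragments,n_asymmetric,fraction_asymmetric,ei_mean,ei_median,n_skipped,flags
0,0.0,8,2,2,25.0,0.37599...,0.38101...,0,
1,0.1,8,2,1,12.5,0.32955...,0.33277...,0,
```

and `report/per_cell.csv` the per-cell scores, half-curve areas, nadir
angles, and EI values. The same pipeline is available as a library
(`rbcmorph.analyze_frames`, `rbcmorph.score_mask`), and the calibration step
as a scikit-learn estimator (`rbcmorph.AsymmetryThresholdClassifier`).

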