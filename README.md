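# uristrip

Automated colorimetric grading of urine test strips (dipsticks) from
photographs, with the diagnostic evaluation statistics used to validate
such readers against automated urine analyzers.

## The problem

A urinalysis strip carries up to 12 reagent pads (protein, glucose,
urobilinogen, bilirubin, ketone, specific gravity, occult blood, pH,
leukocytes, nitrite, creatinine, albumin) whose colors change with analyte
concentration.  Reading them by eye against the manufacturer's reference
chart is subjective: lighting, vision, and the assessor's state all bias
the call.  `uristrip` implements the objective reading: photograph the
reacted strip *next to its reference chart* under fixed lighting, and let
the program pick, for every pad, the chart color block that is perceptually
closest.  Because chart and strip share one imaging path, global
illumination changes cancel out of the comparison and no per-session color
calibration is needed.

## Method

For a scene image `I` and a chart layout (patch/pad coordinates in template
space, ordered grade labels per analyte):

1. **Registration** — detect scale/rotation/lighting-robust keypoints
   (SIFT, a nonlinear multi-scale detector of the KAZE/AKAZE family) in the
   scene and in the layout's template, match descriptors with Lowe's ratio
   test (0.75) plus cross-check, and estimate an 8-DOF projective
   homography H (scene → template) by RANSAC (3 px reprojection tolerance).
   The scene is resampled into template space by bilinear interpolation.
2. **Sampling** — the mean RGB of the central 10×10 px window of every
   strip pad and every chart patch, rounded half-up to 8 bits.
3. **Color space** — sRGB → linear RGB (0.04045 breakpoint) → XYZ → CIELAB
   (D65/2°).
4. **Judgment** — for each analyte, the pad is graded as
   `argmin_k ΔE00(pad, patch_k)` where ΔE00 is the full CIEDE2000
   color-difference formula ("approximate selection"); ties break toward
   the lower grade.  Round-down/round-up readings (floor/ceiling of the
   pad's fractional position along the grade-color polyline in Lab space)
   are selectable alternatives.
5. **Evaluation** — given paired program-vs-analyzer grades: exact and
   ±1-rank concordance per analyte with an unweighted cross-analyte mean;
   sensitivity `TP/(TP+FN)` and specificity `TN/(TN+FP)` at a binary
   disease threshold (e.g. albumin ≥ 30 mg/L, the microalbuminuria rule);
   ROC curve and tie-corrected (Mann–Whitney) AUC.

A synthetic scene generator renders chart+strip scenes with known
ground-truth grades under perspective warp, illumination gain, pad-color
offsets and Gaussian sensor noise, so the whole pipeline is testable
without clinical specimens.  Its 12-analyte demo layout uses plausible
placeholder ramps, not any manufacturer's proprietary chart colors.

## Worked example

Render one ground-truth scene (10 % perspective warp, σ = 2 sensor noise)
and grade it:

```sh
$ uristrip simulate --n 1 --noise-sigma 2 --warp-frac 0.1 --seed 42 --out-dir demo
wrote 1 scene(s) to demo
$ uristrip judge demo/s0000.png --template demo/template.png --out-json demo/report.json
protein         3+      0.00
glucose         1+      0.00
urobilinogen    8       0.00
bilirubin       2+      0.00
ketone          -       0.00
specific gravity        1.030   0.00
occult blood    2+      0.00
pH              8       0.00
leukocytes      -       0.80
nitrite         -       0.00
creatinine      50      0.00
albumin         150     0.00
```

Each line is `analyte  chosen grade label  min ΔE00`.  A small minimum
color difference means the pad sat almost exactly on a chart color; every
call above matches `demo/manifest.csv`, the renderer's ground truth.  The
JSON report additionally carries the full ΔE00 vector per analyte and the
registration diagnostics (here 249/262 RANSAC inliers).

Evaluating paired records (CSV with `specimen_id, analyte,
program_label, reference_label` or rank columns) prints a per-analyte
concordance table and, with `--threshold-analyte albumin`, the screening
2×2, sensitivity/specificity and AUC:

```sh
uristrip evaluate records.csv --threshold-analyte albumin --threshold-rank 1
```

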