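# Methods

## Scope and model

`uristrip` reads a photographed urine-strip + reference-chart scene and
grades each reagent pad by nearest perceptual color.  The underlying model
is deliberately simple: under fixed, spatially uniform illumination, the
photographed color of a reagent pad and of its matching chart block differ
only by sensor noise and a shared global gain, so the pad's concentration
grade is the chart block minimizing the CIEDE2000 distance in CIELAB.
Everything else in the package — registration, sampling, statistics,
synthesis — exists to make that comparison well-posed and measurable.

## Color pipeline

Conversions accept 8-bit integer sRGB only; float inputs are rejected
rather than guessed at ([0,1] vs [0,255] ambiguity).  The chain is
standard sRGB: inverse gamma with the 0.04045 breakpoint, the Rec. 709
primaries matrix, CIE 1976 L\*a\*b\* against D65/2° (Y normalized to 100).
D65 is assumed because the target imaging setup is a daylight-balanced
light box; the white point is an argument for other setups.

CIEDE2000 is implemented in full (G chroma correction, wraparound-aware
hue means, S_L/S_C/S_H weights, rotation term R_T), parametric factors
kL = kC = kH = 1.  At zero chroma the hue difference is defined as 0 —
the standard convention, made explicit to avoid NaN on neutral grays.  The
implementation reproduces the 34 published verification pairs (shipped in
`uristrip/data/ciede2000_test_pairs.csv`) to 1e-4 and is cross-checked in
the tests against an independent implementation (scikit-image) on 10,000
random Lab pairs.

## Registration

The scene is aligned to the layout template with a full 8-DOF projective
homography: a handheld phone over a light box is a planar-target/
perspective-camera geometry, for which a homography is exact.  Chart and
strip are registered jointly with one transform (they are rigidly placed
in the same plane).  Defaults are the community-standard values — SIFT
features, Lowe ratio 0.75 with cross-check, RANSAC reprojection threshold
3 px, at least 10 inliers and an inlier ratio of 0.3; the RANSAC seed is a
config field for reproducibility.  SIFT is the detector because it is the
nonlinear-scale-space family's widely available representative in the
scientific Python stack; the detector sits behind a config switch (ORB is
the lightweight alternative) and the contract is only "keypoints +
descriptors robust to scale/rotation/lighting".

Warping into template space uses bilinear interpolation; pixels with no
source data are flagged in a validity mask, and any sampling window that
touches them aborts extraction with the analyte named — a partially
out-of-frame chart must fail loudly, not silently grade against garbage.

## Sampling

Each pad/patch is summarized by the arithmetic mean of a 10×10 px window
(channel-wise, rounded half-up).  For an even window the block is anchored
so the nominal center is the lower-right of the four central pixels, i.e.
`[c − w//2, c − w//2 + w)` per axis — an explicit convention because an
even window has no center pixel.  A median aggregator is available for
scenes with dust or specular glare.  Chart colors are sampled from the
photographed scene, not taken from the layout's nominal values: the
nominal colors serve validation and synthesis only, so that illumination
shifts affect both sides of the comparison equally.

## Judgment

The default (and clinically used) reading is approximate selection:
argmin of ΔE00 over the analyte's grade series, ties toward the lower
rank (a screening tool should not over-call ambiguous pads; ties are
flagged in the result).  The round-down and round-up readings described
for human assessors are visual rules without an agreed numeric form; they
are operationalized as floor/ceiling of the pad's fractional position
along the piecewise-linear path through the grade colors in Lab space
(orthogonal projection onto the nearest segment, clamped to [0, n−1]).
This interpretation is documented as such and is never the default.
Specific gravity runs through the same path as every other analyte even
though color-comparison reading of specific gravity is known to agree
poorly with analyzers; special-casing it is future work, not silently
done.

## Evaluation statistics

Concordance is the percent of records with equal program and reference
rank; ±k concordance relaxes equality to |Δrank| ≤ k (k = 1 by default —
one ordinal step is the screening-relevant tolerance).  The cross-analyte
mean is the unweighted mean over analytes, not pooled over specimens,
matching the "average of N items" convention of clinical concordance
tables; printed percentages round half-up to one decimal.  Note that a
mean recomputed from *already-rounded* per-analyte rates can differ from
a mean of unrounded rates in the final digit.

Sensitivity/specificity come from the 2×2 table at a binary threshold
(program positive iff rank ≥ threshold).  Rates with an empty margin are
errors, not zeros.  ROC points are emitted at every distinct score and
the AUC is the tie-corrected Mann–Whitney statistic (tied pairs count
0.5), computed via scikit-learn and verified in the tests against an
O(n²) all-pairs oracle to 1e-12.  The ROC accepts either ordinal grade
indices or any continuous score; an ordinal score's AUC is generally
larger than the binary reduction's (sens+spec)/2, which the tests assert
as a sanity bound.

## Synthetic scenes

The generator stands in for the physical photography protocol.  It renders
the chart at nominal colors, the strip pads at their assigned grades'
colors, and a textured fiducial ring (fixed-seed random blocks + pixel
noise) around the canvas — flat patches alone would starve any feature
detector; the ring is a fixture artifact, not a claim about real charts.
Degradations, in rendering order: global illumination gain (clipped to
8 bits), projective warp onto a padded canvas (corners displaced up to a
stated fraction of image size), i.i.d. Gaussian channel noise, clipping.
Everything is deterministic given the spec's seed.

Default study conditions used by the acceptance checks: cohorts of n = 200
scenes with uniform grade assignment per analyte, noise σ ∈ {0, 2, 4, 8},
pad-color offsets of 0.5 (half-way toward the neighbouring grade, the
hardest realistic case of an intermediate reaction), warps with corner
displacement up to 15 %, and a disease label of albumin rank ≥ 1 —
mirroring the ≥ 30 mg/L microalbuminuria rule.  These sizes keep the full
recomputation at a few minutes on one CPU while leaving binomial noise on
a 200-scene rate below ~1 percentage point.

The demo palette is authored for this package: 12 analytes with 2–7
grades whose ramps darken/hue-shift plausibly.  Channels are scaled so the
brightest patch stays at 200: nearest-color judgment is only
illumination-invariant while no channel clips, so the palette leaves
saturation headroom for the tested ±25 % gain range — the synthetic
equivalent of exposing the photograph correctly.  Adjacent grades are
separated by 4–26 ΔE00 (min 4.2), comfortably above the layout validator's
0.5 floor.

What the generator does **not** emulate: reaction kinetics and read-time
effects, non-uniform illumination, shadows and specular glare, lens
distortion, demosaicing and shot noise, strip batch variation, and the
true colors of any commercial chart.  Passing on synthetic cohorts
therefore demonstrates the correctness of the *reading machinery*, not
clinical performance; the clinical per-analyte concordance table and the
albumin 2×2 bundled in `uristrip/data/` are fixed reference inputs, and
the package's own clinical accuracy on new specimens is out of scope.

With identity warp the cohort runner samples the rendered scene directly
in template space; registration is exercised separately (and at scale) by
the warp-recovery checks, so re-running feature matching on hundreds of
identity-warped scenes would add runtime without information.

## Numerical choices

- Percent rounding: decimal half-up at 1 decimal (`round_half_up`), not
  banker's rounding — matches how clinical tables print.
- Patch sampling rounds channel means half-up to integers.
- ΔE00 ties (exact equality of floats) break to the lower rank and set a
  `tied` flag.
- Homographies are normalized to H[2,2] = 1 and rejected when
  |det| < 1e-12.
- The fractional-position projection treats zero-length segments
  (coincident grade colors — rejected at layout validation anyway) as
  distance-to-point with t = 0.
- Registration failure is an exception carrying diagnostic counts, never a
  silent identity fallback.

## Known limitations

- Single-strip, single-chart scenes only; no automatic chart detection
  without a layout file, no OCR of grade labels.
- No reflectance-based quantitation and no albumin/creatinine ratio
  correction; grades are ordinal, not concentrations.
- The registration contract assumes the scene shares the template's
  resolution regime; extreme scale changes (> ~4×) are untested.
- CIE76/CIE94/CMC color differences and ICC camera profiles are out of
  scope.
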